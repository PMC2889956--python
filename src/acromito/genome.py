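"""Data model for annotated vertebrate mitogenomes.

A mitogenome is modelled as an ordered list of features over a controlled
vocabulary of 39 elements: the 37 genes (13 proteins, 22 tRNAs named by
their one-letter amino-acid code with the UUR/CUN and UCN/AGY leucine and
serine isoacceptors disambiguated, 2 rRNAs), the control region (CR) and
the putative light-strand replication origin (OL).  Coordinates are 1-based
inclusive on the circular genome (GenBank convention); the heavy strand is
written H / "+", the light strand L / "-".  Gene-order comparison is always
performed after linearization of the circular order at a fixed anchor
(tRNA-Phe by default, the conventional first gene of the vertebrate map).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "PROTEIN_GENES",
    "RRNA_GENES",
    "TRNA_GENES",
    "NONCODING_ELEMENTS",
    "VOCABULARY",
    "GeneFeature",
    "MitogenomeRecord",
    "GeneOrder",
    "canonical_vertebrate_order",
    "linearize",
    "mean_cr_length",
    "read_gene_order_table",
    "write_gene_order_table",
    "read_genbank_features",
    "base_symbol",
]

PROTEIN_GENES = (
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
    "COI", "COII", "COIII", "ATP6", "ATP8", "CYTB",
)
RRNA_GENES = ("12S", "16S")
TRNA_GENES = (
    "F", "V", "L(UUR)", "I", "Q", "M", "W", "A", "N", "C", "Y",
    "S(UCN)", "D", "K", "G", "R", "H", "S(AGY)", "L(CUN)", "E", "T", "P",
)
NONCODING_ELEMENTS = ("CR", "OL")

VOCABULARY = frozenset(PROTEIN_GENES + RRNA_GENES + TRNA_GENES + NONCODING_ELEMENTS)

_CLASS_OF = {}
_CLASS_OF.update({g: "protein" for g in PROTEIN_GENES})
_CLASS_OF.update({g: "rRNA" for g in RRNA_GENES})
_CLASS_OF.update({g: "tRNA" for g in TRNA_GENES})
_CLASS_OF.update({g: "noncoding" for g in NONCODING_ELEMENTS})

FEATURE_CLASSES = ("protein", "tRNA", "rRNA", "noncoding")


def base_symbol(name: str) -> str:
    """Strip a duplicate suffix: ``CR-2`` -> ``CR``.  Plain names pass through."""
    if "-" in name:
        head, _, tail = name.rpartition("-")
        if head in VOCABULARY and tail.isdigit():
            return head
    return name


def feature_class_of(name: str) -> str:
    base = base_symbol(name)
    try:
        return _CLASS_OF[base]
    except KeyError:
        raise ValueError(f"unknown gene symbol: {name!r}") from None


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on the circular genome (1-based inclusive)."""

    name: str
    start: int
    end: int
    strand: str
    feature_class: str = ""

    def __post_init__(self):
        if base_symbol(self.name) not in VOCABULARY:
            raise ValueError(f"unknown gene symbol: {self.name!r}")
        if self.start < 1:
            raise ValueError(f"{self.name}: start must be >= 1, got {self.start}")
        if self.strand not in ("H", "L"):
            raise ValueError(f"{self.name}: strand must be H or L, got {self.strand!r}")
        if not self.feature_class:
            object.__setattr__(self, "feature_class", feature_class_of(self.name))
        elif self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"{self.name}: bad feature class {self.feature_class!r}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def orientation(self) -> str:
        return "+" if self.strand == "H" else "-"


@dataclass
class MitogenomeRecord:
    """An annotated mitogenome for one taxon.

    ``cr_length`` is None when the control region could not be fully
    sequenced (extensive tandem repeats); such taxa are excluded from
    family CR-length means.  ``extras`` carries per-taxon metadata that is
    not itself a feature (accession, OL status, tRNA-Pro anticodon ...).
    """

    taxon: str
    family: str = "other"
    features: list = field(default_factory=list)
    genome_length: Optional[int] = None
    cr_length: Optional[int] = None
    circular: bool = True
    sequence: Optional[str] = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        if self.sequence is not None:
            glen = self.genome_length or len(self.sequence)
            for f in self.features:
                if f.end > glen:
                    raise ValueError(
                        f"{self.taxon}: feature {f.name} ends at {f.end} "
                        f"beyond genome length {glen}"
                    )

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


@dataclass(frozen=True)
class GeneOrder:
    """A signed, linearized gene order: tuple of (name, orientation) pairs."""

    elements: tuple
    anchor: str = "F"

    def __post_init__(self):
        object.__setattr__(self, "elements", tuple(tuple(e) for e in self.elements))
        counts = {}
        for name, orient in self.elements:
            if orient not in ("+", "-"):
                raise ValueError(f"bad orientation {orient!r} for {name}")
            if base_symbol(name) not in VOCABULARY:
                raise ValueError(f"unknown gene symbol: {name!r}")
            counts[name] = counts.get(name, 0) + 1
        dups = [n for n, c in counts.items() if c > 1]
        if dups:
            raise ValueError(f"duplicate element names (suffix them): {dups}")

    def names(self) -> tuple:
        return tuple(name for name, _ in self.elements)

    def index(self, name: str) -> int:
        for i, (n, _) in enumerate(self.elements):
            if n == name:
                return i
        raise KeyError(name)

    def orientation(self, name: str) -> str:
        return self.elements[self.index(name)][1]

    def reanchor(self, anchor: str) -> "GeneOrder":
        """Rotate the circular order so `anchor` becomes element 1."""
        idx = _resolve_anchor(self.names(), anchor)
        rotated = self.elements[idx:] + self.elements[:idx]
        return GeneOrder(elements=rotated, anchor=anchor)

    def __len__(self):
        return len(self.elements)


def _resolve_anchor(names: Sequence[str], anchor: str) -> int:
    if anchor in names:
        return names.index(anchor)
    hits = [i for i, n in enumerate(names) if base_symbol(n) == anchor]
    if len(hits) == 1:
        return hits[0]
    if not hits:
        raise KeyError(f"anchor {anchor!r} not present in order")
    raise KeyError(f"anchor {anchor!r} is ambiguous (duplicated element)")


_CANONICAL = (
    ("F", "+"), ("12S", "+"), ("V", "+"), ("16S", "+"), ("L(UUR)", "+"),
    ("ND1", "+"), ("I", "+"), ("Q", "-"), ("M", "+"), ("ND2", "+"),
    ("W", "+"), ("A", "-"), ("N", "-"), ("OL", "+"), ("C", "-"), ("Y", "-"),
    ("COI", "+"), ("S(UCN)", "-"), ("D", "+"), ("COII", "+"), ("K", "+"),
    ("ATP8", "+"), ("ATP6", "+"), ("COIII", "+"), ("G", "+"), ("ND3", "+"),
    ("R", "+"), ("ND4L", "+"), ("ND4", "+"), ("H", "+"), ("S(AGY)", "+"),
    ("L(CUN)", "+"), ("ND5", "+"), ("ND6", "-"), ("E", "-"), ("CYTB", "+"),
    ("T", "+"), ("P", "-"), ("CR", "+"),
)


def canonical_vertebrate_order() -> GeneOrder:
    """The typical vertebrate mitochondrial gene order, linearized at tRNA-Phe.

    39 elements: the 37 genes plus OL and the CR.  Heavy-strand genes are
    "+", light-strand genes "-".
    """
    return GeneOrder(elements=_CANONICAL, anchor="F")


def linearize(record: MitogenomeRecord, anchor: str = "F") -> GeneOrder:
    """Linearize a circular annotated genome at `anchor` (default tRNA-Phe).

    Features are taken in genome-coordinate order and rotated so the anchor
    is element 1; strand H maps to "+", L to "-".  Linearizing twice at the
    same anchor is the identity.
    """
    elems = tuple((f.name, f.orientation) for f in record.features)
    names = tuple(n for n, _ in elems)
    idx = _resolve_anchor(names, anchor)
    return GeneOrder(elements=elems[idx:] + elems[:idx], anchor=anchor)


def mean_cr_length(records: Iterable[MitogenomeRecord], family: str):
    """Arithmetic mean control-region length (bp) for one family.

    Taxa with no resolved CR length are excluded before averaging.  The
    mean is rounded to the nearest integer, ties away from zero.  Returns
    ``(mean_bp, n_included)``.
    """
    lengths = [r.cr_length for r in records
               if r.family == family and r.cr_length is not None]
    if not lengths:
        raise ValueError(f"no records with a resolved CR length for family {family!r}")
    mean = sum(lengths) / len(lengths)
    rounded = int(math.floor(mean + 0.5)) if mean >= 0 else -int(math.floor(-mean + 0.5))
    return rounded, len(lengths)


# ---------------------------------------------------------------------------
# Gene-order TSV

_TSV_HEADER = ["taxon", "family", "gene", "start", "end", "strand", "class"]

#: keys allowed in ``meta:`` rows (value stored in the `start` column)
_META_KEYS = {"accession", "genome_length", "cr_length", "ol_status",
              "anticodon", "note"}
_INT_META = {"genome_length", "cr_length"}


class GeneOrderTableError(ValueError):
    pass


def read_gene_order_table(path) -> list:
    """Read per-taxon annotated gene orders from a TSV file.

    Columns: taxon, family, gene, start, end, strand, class — one row per
    feature, in any taxon order (features for one taxon may be scattered).
    Rows whose gene column is ``meta:<key>`` carry per-taxon metadata in the
    `start` column.  Unknown gene symbols or malformed coordinates raise
    :class:`GeneOrderTableError` naming the offending line.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GeneOrderTableError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header != _TSV_HEADER:
        missing = [c for c in _TSV_HEADER if c not in header]
        raise GeneOrderTableError(
            f"{path}: line 1: bad header (missing columns {missing})" if missing
            else f"{path}: line 1: header columns out of order: {header}")

    feats: dict = {}
    meta: dict = {}
    order_seen: list = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != len(_TSV_HEADER):
            raise GeneOrderTableError(
                f"{path}: line {lineno}: expected {len(_TSV_HEADER)} columns, "
                f"got {len(cols)}")
        taxon, family, gene, start, end, strand, fclass = cols
        if taxon not in feats:
            feats[taxon] = []
            meta[taxon] = {"family": family}
            order_seen.append(taxon)
        if gene.startswith("meta:"):
            key = gene[5:]
            if key not in _META_KEYS:
                raise GeneOrderTableError(
                    f"{path}: line {lineno}: unknown metadata key {key!r}")
            value = start
            if key in _INT_META:
                if value in ("", "-"):
                    value = None
                else:
                    try:
                        value = int(value)
                    except ValueError:
                        raise GeneOrderTableError(
                            f"{path}: line {lineno}: non-numeric {key}: "
                            f"{start!r}") from None
            meta[taxon][key] = value
            continue
        if base_symbol(gene) not in VOCABULARY:
            raise GeneOrderTableError(
                f"{path}: line {lineno}: unknown gene symbol {gene!r}")
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise GeneOrderTableError(
                f"{path}: line {lineno}: non-numeric coordinates "
                f"{start!r}..{end!r}") from None
        try:
            feats[taxon].append(GeneFeature(gene, start_i, end_i, strand, fclass))
        except ValueError as exc:
            raise GeneOrderTableError(f"{path}: line {lineno}: {exc}") from None

    records = []
    for taxon in order_seen:
        m = meta[taxon]
        records.append(MitogenomeRecord(
            taxon=taxon,
            family=m.pop("family"),
            features=feats[taxon],
            genome_length=m.pop("genome_length", None),
            cr_length=m.pop("cr_length", None),
            extras=m,
        ))
    return records


def write_gene_order_table(records: Iterable[MitogenomeRecord], path) -> None:
    """Write records as gene-order TSV; reading it back reproduces them."""
    out = ["\t".join(_TSV_HEADER)]
    for r in records:
        meta_items = []
        if r.genome_length is not None:
            meta_items.append(("genome_length", r.genome_length))
        meta_items.append(("cr_length", "-" if r.cr_length is None else r.cr_length))
        meta_items += sorted(r.extras.items())
        for key, value in meta_items:
            out.append("\t".join([r.taxon, r.family, f"meta:{key}",
                                  str(value), "", "", ""]))
        for f in r.features:
            out.append("\t".join([r.taxon, r.family, f.name, str(f.start),
                                  str(f.end), f.strand, f.feature_class]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# GenBank reader

#: default synonym table mapping common GenBank gene/product spellings to the
#: controlled vocabulary.  Keys are matched case-insensitively after stripping
#: whitespace.  The numbered isoacceptor convention is trnL1 = Leu(CUN),
#: trnL2 = Leu(UUR), trnS1 = Ser(AGY), trnS2 = Ser(UCN).
DEFAULT_SYNONYMS = {
    "12s ribosomal rna": "12S", "s-rrna": "12S", "rrns": "12S", "12s rrna": "12S",
    "small subunit ribosomal rna": "12S",
    "16s ribosomal rna": "16S", "l-rrna": "16S", "rrnl": "16S", "16s rrna": "16S",
    "large subunit ribosomal rna": "16S",
    "d-loop": "CR", "control region": "CR", "cr": "CR",
    "rep_origin": "OL", "ol": "OL", "l-strand origin": "OL",
    "origin of l-strand replication": "OL",
    "nd1": "ND1", "nad1": "ND1", "nadh dehydrogenase subunit 1": "ND1",
    "nd2": "ND2", "nad2": "ND2", "nadh dehydrogenase subunit 2": "ND2",
    "nd3": "ND3", "nad3": "ND3", "nadh dehydrogenase subunit 3": "ND3",
    "nd4": "ND4", "nad4": "ND4", "nadh dehydrogenase subunit 4": "ND4",
    "nd4l": "ND4L", "nad4l": "ND4L", "nadh dehydrogenase subunit 4l": "ND4L",
    "nd5": "ND5", "nad5": "ND5", "nadh dehydrogenase subunit 5": "ND5",
    "nd6": "ND6", "nad6": "ND6", "nadh dehydrogenase subunit 6": "ND6",
    "coi": "COI", "cox1": "COI", "co1": "COI",
    "cytochrome c oxidase subunit i": "COI",
    "coii": "COII", "cox2": "COII", "co2": "COII",
    "cytochrome c oxidase subunit ii": "COII",
    "coiii": "COIII", "cox3": "COIII", "co3": "COIII",
    "cytochrome c oxidase subunit iii": "COIII",
    "atp6": "ATP6", "atpase6": "ATP6", "atp synthase f0 subunit 6": "ATP6",
    "atp8": "ATP8", "atpase8": "ATP8", "atp synthase f0 subunit 8": "ATP8",
    "cytb": "CYTB", "cob": "CYTB", "cytochrome b": "CYTB",
    "trnf": "F", "trna-phe": "F",
    "trnv": "V", "trna-val": "V",
    "trnl1": "L(CUN)", "trna-leu(cun)": "L(CUN)",
    "trnl2": "L(UUR)", "trna-leu(uur)": "L(UUR)",
    "trni": "I", "trna-ile": "I",
    "trnq": "Q", "trna-gln": "Q",
    "trnm": "M", "trna-met": "M",
    "trnw": "W", "trna-trp": "W",
    "trna": "A", "trna-ala": "A",
    "trnn": "N", "trna-asn": "N",
    "trnc": "C", "trna-cys": "C",
    "trny": "Y", "trna-tyr": "Y",
    "trns1": "S(AGY)", "trna-ser(agy)": "S(AGY)",
    "trns2": "S(UCN)", "trna-ser(ucn)": "S(UCN)",
    "trnd": "D", "trna-asp": "D",
    "trnk": "K", "trna-lys": "K",
    "trng": "G", "trna-gly": "G",
    "trnr": "R", "trna-arg": "R",
    "trnh": "H", "trna-his": "H",
    "trne": "E", "trna-glu": "E",
    "trnt": "T", "trna-thr": "T",
    "trnp": "P", "trna-pro": "P",
}

_GB_TYPES = {"CDS": "protein", "tRNA": "tRNA", "rRNA": "rRNA",
             "D-loop": "noncoding", "rep_origin": "noncoding",
             "misc_feature": "noncoding"}


def read_genbank_features(path, synonyms=None, warn=None) -> MitogenomeRecord:
    """Read one GenBank flat file into a :class:`MitogenomeRecord`.

    Feature gene/product names are mapped to the controlled vocabulary via
    a synonym table (``DEFAULT_SYNONYMS`` merged with `synonyms`);
    unmappable features are reported through `warn` (a callable; default
    collects into the record's ``extras['skipped']``) and skipped.
    Duplicated names are suffixed -1/-2 in genome order.
    """
    from Bio import SeqIO

    table = dict(DEFAULT_SYNONYMS)
    if synonyms:
        table.update({k.strip().lower(): v for k, v in synonyms.items()})

    try:
        gb = SeqIO.read(path, "genbank")
    except Exception as exc:
        raise ValueError(f"{path}: malformed GenBank record: {exc}") from exc

    skipped = []
    feats = []
    for f in gb.features:
        if f.type not in _GB_TYPES:
            if f.type != "source" and f.type != "gene":
                skipped.append(f"{f.type}@{int(f.location.start) + 1}")
            continue
        name = None
        if f.type == "D-loop":
            name = "CR"
        elif f.type == "rep_origin":
            name = "OL"
        else:
            for qual in ("gene", "product", "note"):
                for val in f.qualifiers.get(qual, []):
                    key = val.strip().lower()
                    if key in table:
                        name = table[key]
                        break
                if name:
                    break
        if name is None:
            skipped.append(f"{f.type}@{int(f.location.start) + 1}")
            continue
        strand = "L" if f.location.strand == -1 else "H"
        feats.append(GeneFeature(name, int(f.location.start) + 1,
                                 int(f.location.end), strand))
    feats.sort(key=lambda f: f.start)

    counts = {}
    for f in feats:
        counts[f.name] = counts.get(f.name, 0) + 1
    seen = {}
    suffixed = []
    for f in feats:
        if counts[f.name] > 1:
            seen[f.name] = seen.get(f.name, 0) + 1
            f = replace(f, name=f"{f.name}-{seen[f.name]}")
        suffixed.append(f)

    extras = {}
    message = None
    if skipped:
        extras["skipped"] = skipped
        message = f"{path}: skipped unmappable features: {skipped}"
    elif not suffixed:
        message = f"{path}: no mappable features found"
    if message:
        if warn is not None:
            warn(message)
        else:
            import warnings
            warnings.warn(message)
    return MitogenomeRecord(
        taxon=gb.name or gb.id,
        features=suffixed,
        genome_length=len(gb.seq) if len(gb.seq) else None,
        sequence=str(gb.seq) if len(gb.seq) else None,
        extras=extras,
    )
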