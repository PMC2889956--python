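"""Structural annotation of mitochondrial control regions.

The control region (CR) is treated as three ordered domains: Domain 1
carries ETAS (extended termination-associated sequence) motifs and, in
chamaeleonids, a long tandem-repeat array 5' of them; Domain 2 is the
central conserved region with Boxes C, D and F; Domain 3 carries the
conserved sequence blocks (CSB I/II/III) and the two AT-rich repeat
classes, (AT)n dinucleotide arrays and (A_x T_y)n poly-A/poly-T block
arrays.  Domain boundaries are placed at the 3'-most anchor of each class
(ETAS for 1|2, Boxes for 2|3), falling back to configurable fractional
positions (flagged low-confidence) when an anchor class has no hits.

Motif search is windowed Hamming matching of IUPAC consensus patterns on
the annotated heavy strand.  The default patterns are conventional
vertebrate CR consensus approximations and are fully configurable; no
analysis here depends on their biological accuracy.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

__all__ = [
    "MotifDef",
    "MotifHit",
    "RepeatArray",
    "DomainPartition",
    "CRAnnotation",
    "CRConfig",
    "DEFAULT_MOTIFS",
    "find_motifs",
    "detect_tandem_repeats",
    "classify_at_arrays",
    "partition_domains",
    "cr_profile",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class MotifDef:
    name: str
    pattern: str
    max_mismatches: int = -1     # default: floor(len/5)

    def __post_init__(self):
        if not self.pattern:
            raise ValueError(f"{self.name}: empty pattern")
        bad = [c for c in self.pattern if c not in IUPAC]
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC symbols {bad} in pattern")
        if self.max_mismatches < 0:
            object.__setattr__(self, "max_mismatches", len(self.pattern) // 5)
        if self.max_mismatches >= len(self.pattern):
            raise ValueError(f"{self.name}: max_mismatches >= pattern length")


#: conventional vertebrate CR consensus approximations (configurable; the
#: ETAS blocks carry the TACAT/ATGTA core, the CSBs the C-rich cores).
DEFAULT_MOTIFS = (
    MotifDef("ETAS1", "TACATRWATGTATAAYGT"),
    MotifDef("ETAS2", "TACATAAWTYATGTATAT"),
    MotifDef("BoxF", "GTTYCGTGCAWAGCYTAT"),
    MotifDef("BoxC", "ATACCCCCCAWCTYCCCC"),
    MotifDef("BoxD", "AGGGGTYGGGGGRTTTTC"),
    MotifDef("CSB1", "TTAATGCTTGWYGGACATA"),
    MotifDef("CSB2", "AAACCCCCCCTACCCCCC"),
    MotifDef("CSB3", "TGCCAAACCCCAAAARCC"),
)


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int          # 1-based inclusive on the CR
    end: int
    mismatches: int


@dataclass
class RepeatArray:
    kind: str                       # tandem | AT_dinucleotide | AT_block
    start: int                      # 1-based inclusive
    end: int
    copies: float
    purity: float
    unit: Optional[str] = None      # tandem consensus unit
    profile: Optional[list] = None  # AT_block: list of (x, y) run lengths
    period: Optional[int] = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _seq_ints(seq: str) -> np.ndarray:
    table = np.zeros(256, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    bad = set(chr(c) for c in np.unique(arr)) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
    return table[arr]


def find_motifs(seq: str, motif_defs: Sequence[MotifDef] = DEFAULT_MOTIFS
                ) -> List[MotifHit]:
    """All sufficiently close matches of each motif on the given strand.

    A window is a hit when its Hamming distance to the IUPAC pattern is at
    most the motif's ``max_mismatches`` (an N in the sequence only matches
    a pattern N).  Overlapping hits of the same motif are reduced to the
    lowest-mismatch one (ties: 5'-most).  Hits are 1-based inclusive.
    """
    ints = _seq_ints(seq)
    n = len(ints)
    hits: List[MotifHit] = []
    for motif in motif_defs:
        L = len(motif.pattern)
        if L > n:
            continue
        allowed = np.zeros((L, 5), dtype=bool)
        for j, sym in enumerate(motif.pattern):
            for b in IUPAC[sym]:
                allowed[j, _BASE_INDEX[b]] = True
            if sym == "N":
                allowed[j, 4] = True
        m = n - L + 1
        mism = np.zeros(m, dtype=np.int32)
        for j in range(L):
            mism += ~allowed[j][ints[j:j + m]]
        raw = [(int(i), int(mism[i])) for i in np.nonzero(mism <= motif.max_mismatches)[0]]
        # reduce overlap chains
        cluster: List[Tuple[int, int]] = []
        for start, mm in raw + [(n + L, 0)]:
            if cluster and start >= cluster[-1][0] + L:
                best = min(cluster, key=lambda t: (t[1], t[0]))
                hits.append(MotifHit(motif.name, best[0] + 1, best[0] + L, best[1]))
                cluster = []
            if start <= n - L:
                cluster.append((start, mm))
    hits.sort(key=lambda h: (h.start, h.motif))
    return hits


# ---------------------------------------------------------------------------
# tandem repeats


def _dense_regions(match: np.ndarray, min_identity: float,
                   min_true: int) -> List[Tuple[int, int]]:
    """High-identity [a, b) intervals of a boolean array.

    Maximal-scoring-segment scan with score (1 - t) per match and -t per
    mismatch, t = min_identity: any segment of positive score has identity
    above t, and the running maximum ends at the last informative match, so
    segment boundaries do not drift into random background.  Segments with
    fewer than `min_true` matches are dropped.
    """
    score = np.where(match, 1.0 - min_identity, -min_identity)
    regions = []
    run = 0.0
    seg_start = 0
    best = 0.0
    best_end = -1
    ones = 0
    best_ones = 0
    for i, s in enumerate(score):
        if run <= 0 and s > 0:
            seg_start, run, best, best_end = i, 0.0, 0.0, -1
            ones = best_ones = 0
        run += s
        if s > 0:
            ones += 1
        if run > best:
            best, best_end, best_ones = run, i, ones
        if run <= 0 or i == len(score) - 1:
            if best_end >= 0 and best_ones >= min_true:
                regions.append((seg_start, best_end + 1))
            run = min(run, 0.0)
            best, best_end = 0.0, -1
    return regions


def _extend_region(match, a: int, b: int, p: int,
                   min_identity: float):
    """Make a dense region maximal: push each edge outward by the longest
    adjacent block (up to one period) whose identity stays at or above the
    threshold, then trim the edges back to match positions.  Random
    background (~25% positional identity) never qualifies, so edges do not
    drift; noisy true-array edges do get reattached."""
    n = len(match)
    moved = True
    while moved:
        moved = False
        for e in range(min(p, n - b), 0, -1):
            if match[max(b - p, a):b + e].mean() >= min_identity:
                b += e
                moved = True
                break
        for e in range(min(p, a), 0, -1):
            if match[a - e:min(a + p, b)].mean() >= min_identity:
                a -= e
                moved = True
                break
    while a < b and not match[a]:
        a += 1
    while b > a and not match[b - 1]:
        b -= 1
    return int(a), int(b)


def detect_tandem_repeats(seq: str, min_period: int = 1,
                          max_period: Optional[int] = None,
                          min_copies: int = 3,
                          min_identity: float = 0.85) -> List[RepeatArray]:
    """Detect tandem repeat arrays by period-wise self-match profiles.

    For each period p the boolean profile ``s[i] == s[i+p]`` is scanned for
    dense regions (positional identity >= ``min_identity``); a region of
    match length m spans m + p sequence positions, i.e. (m + p) / p copies
    (fractional copies allowed).  Arrays re-detected at a multiple of a
    smaller period are suppressed (smallest period wins).
    """
    ints = _seq_ints(seq)
    n = len(ints)
    if max_period is None:
        max_period = max(min_period, n // max(min_copies, 1))
    arrays: List[RepeatArray] = []
    for p in range(min_period, min(max_period, n - 1) + 1):
        match = ints[:-p] == ints[p:]
        min_true = max((min_copies - 1) * p, 1)
        for a, b in _dense_regions(match, min_identity, min_true):
            a, b = _extend_region(match, a, b, p, min_identity)
            start, end = a, b + p          # sequence span, 0-based half open
            copies = (end - start) / p
            if copies < min_copies:
                continue
            unit_chars = []
            bases = "ACGTN"
            for ph in range(p):
                col = ints[start + ph:end:p]
                unit_chars.append(bases[np.bincount(col, minlength=5).argmax()])
            unit = "".join(unit_chars)
            perfect = (unit * (int(np.ceil(copies)) + 1))[:end - start]
            purity = float(np.mean([seq[start + k].upper() == perfect[k]
                                    for k in range(end - start)]))
            arrays.append(RepeatArray("tandem", start + 1, end, round(copies, 2),
                                      round(purity, 4), unit=unit, period=p))
    # smallest-period-wins suppression
    arrays.sort(key=lambda r: (r.period, r.start))
    kept: List[RepeatArray] = []
    for r in arrays:
        redundant = False
        for q in kept:
            if r.period % q.period == 0 or r.period == q.period:
                ov = min(r.end, q.end) - max(r.start, q.start) + 1
                if ov >= 0.8 * r.length:
                    redundant = True
                    break
        if not redundant:
            kept.append(r)
    kept.sort(key=lambda r: r.start)
    return kept


# ---------------------------------------------------------------------------
# AT-rich arrays

_AT_BLOCK_RE = re.compile(r"(?:A{2,}T{2,}){2,}")
_AT_BLOCK_UNIT_RE = re.compile(r"(A{2,})(T{2,})")


def _alternating_runs(seq: str) -> List[Tuple[int, int]]:
    """Maximal 0-based half-open runs of strictly alternating A/T."""
    runs = []
    n = len(seq)
    i = 0
    while i < n - 1:
        if seq[i] in "AT" and seq[i + 1] in "AT" and seq[i] != seq[i + 1]:
            j = i + 1
            while j + 1 < n and seq[j + 1] in "AT" and seq[j + 1] != seq[j]:
                j += 1
            runs.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return runs


def classify_at_arrays(seq: str, min_len: int = 20, min_copies: int = 3,
                       max_impurity: float = 0.0) -> List[RepeatArray]:
    """Find and classify the two AT-rich repeat classes.

    AT_dinucleotide: maximal strictly alternating (AT)n / (TA)n runs with
    at least `min_copies` dinucleotide copies.  AT_block: maximal
    concatenations of >= 2 blocks each matching A^x T^y with x, y >= 2.
    Regions shorter than `min_len` are discarded; a region qualifying as
    both is reported as AT_dinucleotide (the stricter pattern).  With
    ``max_impurity`` > 0, neighbouring runs of the same kind are merged
    across short gaps while the merged impurity stays within bound.
    """
    seq = seq.upper()
    arrays: List[RepeatArray] = []

    din_runs = _alternating_runs(seq)
    din_runs = _merge_runs(din_runs, max_impurity)
    din_spans = []
    for a, b in din_runs:
        copies = (b - a) // 2
        if b - a >= min_len and copies >= min_copies:
            pure = sum(r1 - r0 for r0, r1 in _alternating_runs(seq[a:b]))
            purity = pure / (b - a)
            arrays.append(RepeatArray("AT_dinucleotide", a + 1, b, copies,
                                      round(purity, 4), unit=seq[a:a + 2],
                                      period=2))
            din_spans.append((a, b))

    for m in _AT_BLOCK_RE.finditer(seq):
        a, b = m.start(), m.end()
        if b - a < min_len:
            continue
        if any(a < d1 and d0 < b for d0, d1 in din_spans):
            continue                      # dinucleotide takes precedence
        profile = [(len(x), len(y))
                   for x, y in _AT_BLOCK_UNIT_RE.findall(m.group(0))]
        if len(profile) < 2:
            continue
        arrays.append(RepeatArray("AT_block", a + 1, b, len(profile), 1.0,
                                  profile=profile))
    arrays.sort(key=lambda r: r.start)
    return arrays


def _merge_runs(runs: List[Tuple[int, int]], max_impurity: float
                ) -> List[Tuple[int, int]]:
    if max_impurity <= 0 or not runs:
        return runs
    merged = [runs[0]]
    for a, b in runs[1:]:
        pa, pb = merged[-1]
        span = b - pa
        covered = (pb - pa) + (b - a)
        if (span - covered) / span <= max_impurity:
            merged[-1] = (pa, b)
        else:
            merged.append((a, b))
    return merged


# ---------------------------------------------------------------------------
# domains


@dataclass
class DomainPartition:
    domain1: Tuple[int, int]
    domain2: Tuple[int, int]
    domain3: Tuple[int, int]
    low_confidence: bool = False
    missing_anchors: list = field(default_factory=list)

    def __iter__(self):
        return iter((self.domain1, self.domain2, self.domain3))


_ETAS_NAMES = ("ETAS1", "ETAS2")
_BOX_NAMES = ("BoxC", "BoxD", "BoxF")


def partition_domains(seq: str, hits: Sequence[MotifHit],
                      fallback_fractions: Tuple[float, float] = (0.30, 0.65),
                      on_disorder: str = "error") -> DomainPartition:
    """Partition a CR into its three domains from anchor motif hits.

    Domain 1 runs from the 5' end through the 3'-most ETAS hit; Domain 2
    from there through the 3'-most of Boxes C/D/F; Domain 3 is the
    remainder.  A missing anchor class falls back to the configured
    fractional position and flags the partition low-confidence.  Anchors
    out of canonical order (a Box ending before the last ETAS) raise, or
    flag when ``on_disorder="flag"``.
    """
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    etas_end = max((h.end for h in hits if h.motif in _ETAS_NAMES), default=None)
    box_end = max((h.end for h in hits if h.motif in _BOX_NAMES), default=None)
    missing = []
    low = False
    if etas_end is None:
        missing.append("ETAS")
        etas_end = max(1, round(n * fallback_fractions[0]))
        low = True
    if box_end is None:
        missing.append("Box")
        box_end = max(etas_end + 1, round(n * fallback_fractions[1]))
        low = True
    if box_end <= etas_end:
        if on_disorder == "error":
            raise ValueError(
                f"anchors out of canonical order: last Box ends at {box_end}, "
                f"last ETAS at {etas_end}")
        low = True
        box_end = min(n - 1, etas_end + 1)
    etas_end = min(etas_end, n - 2)
    box_end = min(box_end, n - 1)
    return DomainPartition(
        domain1=(1, etas_end),
        domain2=(etas_end + 1, box_end),
        domain3=(box_end + 1, n),
        low_confidence=low,
        missing_anchors=missing,
    )


# ---------------------------------------------------------------------------
# whole-CR profile


@dataclass
class CRConfig:
    motifs: tuple = DEFAULT_MOTIFS
    tandem_min_period: int = 10
    tandem_max_period: Optional[int] = 200
    tandem_min_copies: int = 3
    tandem_min_identity: float = 0.85
    at_min_len: int = 20
    at_min_copies: int = 3
    at_max_impurity: float = 0.0
    fallback_fractions: Tuple[float, float] = (0.30, 0.65)
    on_disorder: str = "flag"

    def to_yaml(self) -> str:
        d = {
            "motifs": [{"name": m.name, "pattern": m.pattern,
                        "max_mismatches": m.max_mismatches}
                       for m in self.motifs],
            "tandem": {"min_period": self.tandem_min_period,
                       "max_period": self.tandem_max_period,
                       "min_copies": self.tandem_min_copies,
                       "min_identity": self.tandem_min_identity},
            "at": {"min_len": self.at_min_len, "min_copies": self.at_min_copies,
                   "max_impurity": self.at_max_impurity},
            "domains": {"fallback_fractions": list(self.fallback_fractions),
                        "on_disorder": self.on_disorder},
        }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CRConfig":
        d = yaml.safe_load(text)
        motifs = tuple(MotifDef(m["name"], m["pattern"],
                                m.get("max_mismatches", -1))
                       for m in d.get("motifs", []))
        t = d.get("tandem", {})
        a = d.get("at", {})
        dom = d.get("domains", {})
        return cls(
            motifs=motifs or DEFAULT_MOTIFS,
            tandem_min_period=t.get("min_period", 10),
            tandem_max_period=t.get("max_period", 200),
            tandem_min_copies=t.get("min_copies", 3),
            tandem_min_identity=t.get("min_identity", 0.85),
            at_min_len=a.get("min_len", 20),
            at_min_copies=a.get("min_copies", 3),
            at_max_impurity=a.get("max_impurity", 0.0),
            fallback_fractions=tuple(dom.get("fallback_fractions", (0.30, 0.65))),
            on_disorder=dom.get("on_disorder", "flag"),
        )


@dataclass
class CRAnnotation:
    length: int
    domains: DomainPartition
    motif_hits: list
    repeat_arrays: list
    trnp_interval: Optional[Tuple[int, int]] = None
    context_labels: list = field(default_factory=list)  # parallel to repeat_arrays

    def arrays_of_kind(self, kind: str) -> list:
        return [r for r in self.repeat_arrays if r.kind == kind]

    def to_dict(self) -> dict:
        return {
            "length": self.length,
            "domains": {"domain1": list(self.domains.domain1),
                        "domain2": list(self.domains.domain2),
                        "domain3": list(self.domains.domain3),
                        "low_confidence": self.domains.low_confidence},
            "motif_hits": [vars(h).copy() if not hasattr(h, "__dataclass_fields__")
                           else {"motif": h.motif, "start": h.start,
                                 "end": h.end, "mismatches": h.mismatches}
                           for h in self.motif_hits],
            "repeat_arrays": [
                {"kind": r.kind, "start": r.start, "end": r.end,
                 "copies": r.copies, "purity": r.purity, "unit": r.unit,
                 "profile": r.profile, "period": r.period,
                 "context": lbl}
                for r, lbl in zip(self.repeat_arrays,
                                  self.context_labels or [None] * len(self.repeat_arrays))
            ],
            "trnp_interval": list(self.trnp_interval) if self.trnp_interval else None,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_bed_tsv(self) -> str:
        """BED-like TSV, 1-based inclusive coordinates."""
        lines = ["feature\tstart\tend\tdetail"]
        for name, (s, e) in zip(("domain1", "domain2", "domain3"), self.domains):
            lines.append(f"{name}\t{s}\t{e}\t")
        for h in self.motif_hits:
            lines.append(f"motif:{h.motif}\t{h.start}\t{h.end}\tmm={h.mismatches}")
        for r, lbl in zip(self.repeat_arrays,
                          self.context_labels or [None] * len(self.repeat_arrays)):
            detail = f"copies={r.copies};purity={r.purity}"
            if lbl:
                detail += f";context={lbl}"
            lines.append(f"repeat:{r.kind}\t{r.start}\t{r.end}\t{detail}")
        if self.trnp_interval:
            lines.append(f"trnP\t{self.trnp_interval[0]}\t{self.trnp_interval[1]}\t")
        return "\n".join(lines) + "\n"


def _context_label(array: RepeatArray, trnp: Optional[Tuple[int, int]]) -> str:
    if trnp is None:
        return "no_trnP"
    if array.end < trnp[0]:
        return "5prime"
    if array.start > trnp[1]:
        return "3prime"
    return "overlapping"


def cr_profile(record, config: Optional[CRConfig] = None) -> CRAnnotation:
    """Full structural profile of one control region.

    `record` is the CR sequence itself, or a mapping/object carrying
    ``sequence`` and optionally ``trnp_interval`` (1-based inclusive
    coordinates of an embedded/adjacent tRNA-Pro relative to the CR).
    Each AT-rich array is labelled by its position relative to tRNA-Pro.
    """
    config = config or CRConfig()
    if isinstance(record, str):
        seq, trnp = record, None
    elif isinstance(record, dict):
        seq, trnp = record["sequence"], record.get("trnp_interval")
    else:
        seq = record.sequence
        trnp = getattr(record, "trnp_interval", None)
    if trnp is not None:
        trnp = tuple(trnp)

    hits = find_motifs(seq, config.motifs)
    domains = partition_domains(seq, hits, config.fallback_fractions,
                                config.on_disorder)
    arrays = detect_tandem_repeats(
        seq, config.tandem_min_period, config.tandem_max_period,
        config.tandem_min_copies, config.tandem_min_identity)
    at_arrays = classify_at_arrays(seq, config.at_min_len, config.at_min_copies,
                                   config.at_max_impurity)
    # an AT array re-found by the generic tandem scan is kept once, as AT
    at_spans = [(r.start, r.end) for r in at_arrays]
    arrays = [r for r in arrays
              if not any(r.start <= e and s <= r.end for s, e in at_spans)]
    all_arrays = sorted(arrays + at_arrays, key=lambda r: r.start)
    labels = [_context_label(r, trnp) if r.kind.startswith("AT") else None
              for r in all_arrays]
    return CRAnnotation(
        length=len(seq),
        domains=domains,
        motif_hits=hits,
        repeat_arrays=all_arrays,
        trnp_interval=trnp,
        context_labels=labels,
    )
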