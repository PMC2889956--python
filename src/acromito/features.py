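"""Gene-identification procedures for mitochondrial annotation.

Three small, testable heuristics used when scoring mitogenome features:

* translation under the vertebrate mitochondrial genetic code, accepting
  the abbreviated stop codons T / TA that are completed to TAA by
  polyadenylation of the mature mRNA;
* anticodon extraction from a tRNA gene via a bounded cloverleaf-anchored
  search (a 5-bp anticodon stem enclosing a 7-nt loop whose centre lies in
  the middle third of the gene; the anticodon is loop positions 3-5);
* detection of the light-strand replication-origin (OL) stem-loop in the
  WANCY tRNA cluster (a perfect contiguous stem of configurable minimum
  length enclosing a short loop).

Stems allow Watson-Crick plus G·T (G·U in RNA) wobble pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

__all__ = [
    "MT_CODE",
    "MT_START_CODONS",
    "ABBREVIATED_STOPS",
    "TranslationResult",
    "translate_mt",
    "AnticodonCall",
    "extract_anticodon",
    "HairpinCall",
    "detect_ol_hairpin",
    "pairs",
]

# Vertebrate mitochondrial code, written out from the standard code with its
# four mitochondrial reassignments: AGA/AGG -> stop, ATA -> Met, TGA -> Trp.
_STANDARD = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
_BASES = "TCAG"
MT_CODE = {}
for _i, _aa in enumerate(_STANDARD):
    _codon = _BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]
    MT_CODE[_codon] = _aa
MT_CODE["AGA"] = "*"
MT_CODE["AGG"] = "*"
MT_CODE["ATA"] = "M"
MT_CODE["TGA"] = "W"

MT_START_CODONS = frozenset({"ATG", "ATA", "ATT", "ATC", "GTG"})
ABBREVIATED_STOPS = ("TA", "T")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: allowed stem pairs: Watson-Crick plus G·T wobble (DNA alphabet)
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
          ("G", "T"), ("T", "G")}


def pairs(x: str, y: str) -> bool:
    return (x, y) in _PAIRS


@dataclass
class TranslationResult:
    protein: str
    stop_status: str                 # complete | polyA_completed | none
    internal_stops: tuple = ()       # 1-based codon indices
    start_codon_ok: bool = True

    @property
    def valid(self) -> bool:
        return not self.internal_stops and self.stop_status != "none"


def translate_mt(cds_seq: str, allow_abbreviated_stop: bool = True
                 ) -> TranslationResult:
    """Translate a CDS under the vertebrate mitochondrial code.

    A trailing TAA/TAG/AGA/AGG codon terminates normally; with
    `allow_abbreviated_stop`, a trailing T or TA is accepted as a stop
    completed by polyadenylation and reported as such.  Internal stop
    codons are reported as validation failures (not raised).  Codons
    containing N translate to X.
    """
    seq = cds_seq.upper().replace("U", "T")
    if len(seq) < 3:
        raise ValueError(f"CDS too short to translate ({len(seq)} nt)")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide symbols in CDS: {sorted(bad)}")

    n_full = len(seq) // 3
    remainder = seq[n_full * 3:]
    aas = []
    stop_status = "none"
    internal = []
    for i in range(n_full):
        codon = seq[3 * i: 3 * i + 3]
        aa = MT_CODE.get(codon, "X") if "N" not in codon else "X"
        if aa == "*":
            if i == n_full - 1 and not remainder:
                stop_status = "complete"
            else:
                internal.append(i + 1)
                aas.append("*")
        else:
            aas.append(aa)
    if remainder:
        if allow_abbreviated_stop and remainder in ABBREVIATED_STOPS:
            if stop_status == "none":
                stop_status = "polyA_completed"
        else:
            raise ValueError(
                f"CDS length not a codon multiple and trailing {remainder!r} "
                "is not an abbreviated stop")
    return TranslationResult(
        protein="".join(aas),
        stop_status=stop_status,
        internal_stops=tuple(internal),
        start_codon_ok=seq[:3] in MT_START_CODONS,
    )


# ---------------------------------------------------------------------------
# anticodon extraction


@dataclass
class AnticodonCall:
    anticodon: Optional[str]         # None when undetermined
    confidence: float                # stem pairs / 5
    stem_start: Optional[int] = None  # 1-based start of the 5' stem arm

    @property
    def determined(self) -> bool:
        return self.anticodon is not None


def extract_anticodon(trna_seq: str, min_pairs: int = 4,
                      length_range: Tuple[int, int] = (55, 95)) -> AnticodonCall:
    """Locate the anticodon of a mitochondrial tRNA gene.

    Enumerates candidate anticodon stems — 5-bp arms with at least
    `min_pairs` allowed pairs enclosing a 7-nt loop whose centre lies in
    the middle third of the gene — and reports loop positions 3-5 of the
    best candidate (most pairs; ties 5'-most).  Returns an undetermined
    call, not an exception, when no candidate exists.
    """
    seq = trna_seq.upper().replace("U", "T")
    n = len(seq)
    if not (length_range[0] <= n <= length_range[1]):
        raise ValueError(
            f"sequence length {n} outside the configured tRNA range "
            f"{length_range}")
    lo, hi = n / 3.0, 2.0 * n / 3.0
    best = None
    for i in range(0, n - 17 + 1):
        centre = i + 8                      # middle of the 7-nt loop
        if not (lo <= centre < hi):
            continue
        arm5 = seq[i:i + 5]
        arm3 = seq[i + 12:i + 17]
        npairs = sum(1 for k in range(5) if pairs(arm5[k], arm3[4 - k]))
        if npairs >= min_pairs:
            if best is None or npairs > best[0]:
                best = (npairs, i)
    if best is None:
        return AnticodonCall(anticodon=None, confidence=0.0)
    npairs, i = best
    return AnticodonCall(anticodon=seq[i + 7:i + 10],
                         confidence=npairs / 5.0,
                         stem_start=i + 1)


# ---------------------------------------------------------------------------
# OL hairpin


@dataclass
class HairpinCall:
    present: bool
    stem_start: Optional[int] = None    # 1-based inclusive
    loop_start: Optional[int] = None
    loop_end: Optional[int] = None
    stem_end: Optional[int] = None
    stem_length: int = 0
    loop_length: int = 0


def detect_ol_hairpin(wancy_seq: str, min_stem: int = 6,
                      loop_range: Tuple[int, int] = (3, 20)) -> HairpinCall:
    """Scan a WANCY-cluster region for the OL stem-and-loop structure.

    Looks for a perfect contiguous stem of at least `min_stem` allowed
    pairs enclosing a loop within `loop_range`.  Reports the longest stem
    (ties: 5'-most, then shortest loop).  An empty region yields an absent
    call.  Presence is monotone in `min_stem`: anything found at stem k is
    found at every smaller threshold.
    """
    seq = wancy_seq.upper().replace("U", "T")
    n = len(seq)
    if n == 0:
        return HairpinCall(present=False)
    best = None
    min_loop, max_loop = loop_range
    for i in range(n):
        for loop in range(min_loop, max_loop + 1):
            # grow the stem outward-in: arm5 = seq[i-s+1..i] pairs with
            # arm3 = seq[i+loop+1..i+loop+s] read back inward
            s = 0
            while True:
                p5 = i - s
                p3 = i + loop + 1 + s
                if p5 < 0 or p3 >= n or not pairs(seq[p5], seq[p3]):
                    break
                s += 1
            if s >= min_stem:
                start = i - s + 1
                cand = (s, -start, -loop)
                if best is None or (s, -(start), -loop) > (best[0], -best[1], -best[2]):
                    best = (s, start, loop)
    if best is None:
        return HairpinCall(present=False)
    s, start, loop = best
    loop_start = start + s + 1
    return HairpinCall(
        present=True,
        stem_start=start + 1,
        loop_start=loop_start,
        loop_end=loop_start + loop - 1,
        stem_end=start + 2 * s + loop,
        stem_length=s,
        loop_length=loop,
    )
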