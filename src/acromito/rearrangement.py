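"""Discrete coding of mitochondrial gene-arrangement variation.

Five discrete characters summarise the arrangement differences observed
among iguanian mitogenomes relative to the typical vertebrate order:

C1  order of the tRNA-Ile/Gln/Met cluster (IQM vs the rearranged QIM);
C2  position/orientation of tRNA-Pro: typical (light strand, between
    tRNA-Thr and the CR), inverted in place (heavy strand), or translocated
    to the 3' side of the CR (between the CR and tRNA-Phe);
C3  control-region copy number: single, or a duplicate CR inserted between
    ND5 and ND6;
C4  presence/absence of the light-strand replication-origin stem-loop (OL)
    in the WANCY tRNA cluster;
C5  tRNA-Pro anticodon triplet (usually TGG; CGG in one aberrant lineage).

The module also provides generic signed-order comparison: an LCS-based
difference summary and the oriented breakpoint distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .genome import GeneOrder, base_symbol

__all__ = [
    "ArrangementCharacter",
    "CHARACTERS",
    "CharacterMatrix",
    "OrderDiff",
    "encode_characters",
    "order_diff",
    "breakpoint_distance",
]

MISSING = "?"


@dataclass(frozen=True)
class ArrangementCharacter:
    id: str
    name: str
    states: tuple
    ancestral_state: str
    description: str = ""

    def __post_init__(self):
        if self.ancestral_state not in self.states:
            raise ValueError(
                f"{self.id}: ancestral state {self.ancestral_state!r} "
                f"not in {self.states}")
        if len(self.states) < 2:
            raise ValueError(f"{self.id}: need at least two states")


CHARACTERS: Dict[str, ArrangementCharacter] = {
    "C1": ArrangementCharacter(
        "C1", "IQM_cluster_order", ("IQM", "QIM"), "IQM",
        "relative order of the tRNA-Ile, tRNA-Gln, tRNA-Met genes"),
    "C2": ArrangementCharacter(
        "C2", "trnP_position", ("typical", "inverted", "translocated_3prime_CR"),
        "typical",
        "position and orientation of the tRNA-Pro gene relative to the CR"),
    "C3": ArrangementCharacter(
        "C3", "cr_copy", ("single", "duplicate_ND5_ND6"), "single",
        "control-region copy number and duplicate placement"),
    "C4": ArrangementCharacter(
        "C4", "ol_stem_loop", ("present", "absent"), "present",
        "light-strand replication-origin stem-loop in the WANCY cluster"),
    "C5": ArrangementCharacter(
        "C5", "trnP_anticodon", ("TGG", "CGG"), "TGG",
        "anticodon triplet of the tRNA-Pro gene"),
}

CHARACTER_IDS = tuple(CHARACTERS)


@dataclass
class CharacterMatrix:
    """taxon x character state labels; "?" marks missing data."""

    taxa: list
    states: dict  # taxon -> {char_id: state}
    characters: dict = field(default_factory=lambda: dict(CHARACTERS))

    def __post_init__(self):
        for taxon in self.taxa:
            row = self.states[taxon]
            for cid, state in row.items():
                char = self.characters[cid]
                if state != MISSING and state not in char.states:
                    raise ValueError(
                        f"{taxon}/{cid}: state {state!r} not in {char.states}")

    def column(self, char_id: str) -> dict:
        return {t: self.states[t].get(char_id, MISSING) for t in self.taxa}

    def to_tsv(self) -> str:
        cids = list(self.characters)
        lines = ["\t".join(["taxon"] + cids)]
        for t in self.taxa:
            lines.append("\t".join([t] + [self.states[t].get(c, MISSING)
                                          for c in cids]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str, characters=None) -> "CharacterMatrix":
        characters = dict(characters or CHARACTERS)
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].split("\t")
        cids = header[1:]
        taxa, states = [], {}
        for ln in lines[1:]:
            cols = ln.split("\t")
            taxa.append(cols[0])
            states[cols[0]] = dict(zip(cids, cols[1:]))
        return cls(taxa=taxa, states=states, characters=characters)

    def to_nexus(self) -> str:
        """NEXUS-style characters block with symbolic state labels."""
        cids = list(self.characters)
        lines = ["#NEXUS", "BEGIN DATA;",
                 f"  DIMENSIONS NTAX={len(self.taxa)} NCHAR={len(cids)};",
                 "  FORMAT DATATYPE=STANDARD MISSING=? SYMBOLS=\"0123456789\";",
                 "  CHARSTATELABELS"]
        for i, cid in enumerate(cids, 1):
            ch = self.characters[cid]
            labels = " ".join(ch.states)
            sep = "," if i < len(cids) else ";"
            lines.append(f"    {i} {ch.name} / {labels}{sep}")
        lines.append("  MATRIX")
        for t in self.taxa:
            codes = []
            for cid in cids:
                s = self.states[t].get(cid, MISSING)
                ch = self.characters[cid]
                codes.append(MISSING if s == MISSING else str(ch.states.index(s)))
            lines.append(f"    {t.replace(' ', '_')}  {''.join(codes)}")
        lines += ["  ;", "END;"]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_nexus(cls, text: str, characters=None) -> "CharacterMatrix":
        characters = dict(characters or CHARACTERS)
        cids = list(characters)
        taxa, states = [], {}
        in_matrix = False
        for ln in text.splitlines():
            stripped = ln.strip()
            if stripped.upper() == "MATRIX":
                in_matrix = True
                continue
            if in_matrix:
                if stripped in (";", "END;"):
                    break
                if not stripped:
                    continue
                name, codes = stripped.split()
                taxa.append(name)
                row = {}
                for cid, code in zip(cids, codes):
                    ch = characters[cid]
                    row[cid] = MISSING if code == MISSING else ch.states[int(code)]
                states[name] = row
        return cls(taxa=taxa, states=states, characters=characters)


def _is_cr(name: str) -> bool:
    return base_symbol(name) == "CR"


def encode_characters(order: GeneOrder, ol_status: str = "unknown",
                      anticodon: Optional[str] = None) -> dict:
    """Score the five arrangement characters from a linearized gene order.

    `order` must be linearized at tRNA-Phe.  ``ol_status`` is one of
    present/absent/unknown; `anticodon` is the tRNA-Pro anticodon triplet
    or None.  Unknown inputs yield "?".
    """
    if order.anchor != "F":
        raise ValueError("order must be linearized at tRNA-Phe (anchor F)")
    names = order.names()

    pos = {}
    for needed in ("I", "Q", "M", "T", "P"):
        try:
            pos[needed] = names.index(needed)
        except ValueError:
            raise ValueError(f"gene {needed} absent from order") from None
    cr_positions = [i for i, n in enumerate(names) if _is_cr(n)]

    states = {}
    states["C1"] = "QIM" if pos["Q"] < pos["I"] else "IQM"

    # C2: a CR between T and P means P sits 3' of the CR (the linearization
    # anchor F is element 0, so "between the CR and tRNA-Phe" is the tail of
    # the linear order).  Otherwise P in the T..CR interval is typical (light
    # strand) or inverted in place (heavy strand).
    p_orient = order.orientation("P")
    cr_between = [c for c in cr_positions if pos["T"] < c < pos["P"]]
    if pos["P"] > pos["T"] and cr_between:
        states["C2"] = "translocated_3prime_CR"
    elif pos["P"] > pos["T"]:
        states["C2"] = "inverted" if p_orient == "+" else "typical"
    else:
        raise ValueError(
            "ambiguous tRNA-Pro placement: P precedes T in the linear order "
            f"(P at {pos['P']}, T at {pos['T']})")

    try:
        nd5, nd6 = names.index("ND5"), names.index("ND6")
    except ValueError:
        raise ValueError("ND5/ND6 absent from order") from None
    states["C3"] = ("duplicate_ND5_ND6"
                    if any(nd5 < c < nd6 for c in cr_positions) else "single")

    if ol_status in ("present", "absent"):
        states["C4"] = ol_status
    elif ol_status == "unknown":
        states["C4"] = MISSING
    else:
        raise ValueError(f"ol_status must be present/absent/unknown, got {ol_status!r}")

    if anticodon is None or anticodon == "unknown":
        states["C5"] = MISSING
    elif anticodon in CHARACTERS["C5"].states:
        states["C5"] = anticodon
    else:
        raise ValueError(f"unexpected tRNA-Pro anticodon {anticodon!r}")
    return states


# ---------------------------------------------------------------------------
# Generic signed-order comparison


@dataclass
class OrderDiff:
    moved: list = field(default_factory=list)    # (symbol, ref_pos, obs_pos) 1-based
    inverted: list = field(default_factory=list)
    gained: list = field(default_factory=list)
    lost: list = field(default_factory=list)

    @property
    def identical(self) -> bool:
        return not (self.moved or self.inverted or self.gained or self.lost)


def _lcs_keep(ref: List[str], obs: List[str]) -> set:
    """Names kept by a deterministic LCS of two duplicate-free name lists.

    Ties are broken by preferring to keep the 5'-most reference elements
    fixed (advance the observed sequence first on equal subproblem scores).
    """
    n, m = len(ref), len(obs)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        row, nxt = dp[i], dp[i + 1]
        for j in range(m - 1, -1, -1):
            if ref[i] == obs[j]:
                row[j] = nxt[j + 1] + 1
            else:
                row[j] = max(nxt[j], row[j + 1])
    keep = set()
    i = j = 0
    while i < n and j < m:
        if ref[i] == obs[j] and dp[i][j] == dp[i + 1][j + 1] + 1:
            keep.add(ref[i])
            i += 1
            j += 1
        elif dp[i][j + 1] >= dp[i + 1][j]:
            j += 1          # skip an observed element: keeps ref[i] available
        else:
            i += 1
    return keep


def order_diff(order: GeneOrder, reference: GeneOrder) -> OrderDiff:
    """Summarise how `order` differs from `reference`.

    Symbols only in one order are gained/lost; common symbols with flipped
    orientation are inverted; common symbols off a deterministic longest
    common subsequence (computed on names, ignoring orientation) are moved.
    A symbol may be both moved and inverted.
    """
    if order.anchor != reference.anchor:
        raise ValueError("orders must share a linearization anchor")
    obs_names = list(order.names())
    ref_names = list(reference.names())
    obs_set, ref_set = set(obs_names), set(ref_names)

    diff = OrderDiff()
    diff.gained = [n for n in obs_names if n not in ref_set]
    diff.lost = [n for n in ref_names if n not in obs_set]

    common_ref = [n for n in ref_names if n in obs_set]
    common_obs = [n for n in obs_names if n in ref_set]
    for name in common_ref:
        if order.orientation(name) != reference.orientation(name):
            diff.inverted.append(name)
    keep = _lcs_keep(common_ref, common_obs)
    for name in common_ref:
        if name not in keep:
            diff.moved.append((name, ref_names.index(name) + 1,
                               obs_names.index(name) + 1))
    return diff


def _signed(name: str, orient: str) -> Tuple[str, int]:
    return (name, 1 if orient == "+" else -1)


def _adjacency_set(order: GeneOrder) -> set:
    """Canonical oriented adjacencies of a linearized circular order.

    The junction closing the linearization is included, so the set has
    exactly len(order) adjacencies.  An adjacency (a, b) is identified with
    its reverse-complement reading (-b, -a); the lexicographically smaller
    of the two encodings is stored.
    """
    elems = [_signed(n, o) for n, o in order.elements]
    adjacencies = set()
    for i in range(len(elems)):
        a = elems[i]
        b = elems[(i + 1) % len(elems)]
        fwd = (a, b)
        rev = ((b[0], -b[1]), (a[0], -a[1]))
        adjacencies.add(min(fwd, rev))
    return adjacencies


def breakpoint_distance(order_a: GeneOrder, order_b: GeneOrder) -> int:
    """Oriented breakpoint distance between two circular orders.

    The number of oriented adjacencies of A absent from B (symmetric, since
    both orders carry the same number of adjacencies).  Requires the same
    symbol multiset.
    """
    if sorted(order_a.names()) != sorted(order_b.names()):
        raise ValueError("orders carry different symbol sets")
    set_a = _adjacency_set(order_a)
    set_b = _adjacency_set(order_b)
    return len(set_a - set_b)
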