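"""Seeded synthetic-data generators with ground-truth manifests.

Every generator is deterministic under a fixed seed and returns, alongside
its data, a :class:`TruthManifest` recording exactly what was planted —
rearrangement events on tree branches, motif coordinates, repeat arrays,
anticodons, hairpin positions — so each analyzer can be tested for exact
recovery without any downloaded data.

Gene orders evolve on a rooted tree from the canonical vertebrate
arrangement by discrete planted events (the IQM->QIM swap, tRNA-Pro
inversion or translocation, CR duplication between ND5 and ND6, OL loss,
anticodon change).  Control regions are concatenated from their three
domains with planted motifs, a Domain-1 tandem-repeat array, Domain-3
AT-rich arrays and an embedded tRNA-Pro at a 200-400 bp spacer from the 3'
end, over i.i.d. random background of configurable composition.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .cr import DEFAULT_MOTIFS, IUPAC, MotifDef
from .features import detect_ol_hairpin, extract_anticodon, pairs
from .genome import GeneOrder, canonical_vertebrate_order
from .parsimony import branch_name, read_tree
from .rearrangement import CHARACTERS, CharacterMatrix, encode_characters

__all__ = [
    "TruthManifest",
    "SimulationParams",
    "order_from_states",
    "simulate_arrangements",
    "simulate_cr",
    "simulate_trna",
    "simulate_wancy",
    "random_rooted_tree",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class TruthManifest:
    """What a generator planted, for recovery testing."""

    seed: int
    params: dict = field(default_factory=dict)
    events: list = field(default_factory=list)        # {character, branch, from, to}
    tip_states: dict = field(default_factory=dict)    # taxon -> {char: state}
    motifs: list = field(default_factory=list)        # {name, start, end}
    repeats: list = field(default_factory=list)       # {kind, start, end, ...}
    anticodon: Optional[str] = None
    anticodon_loop: Optional[tuple] = None
    hairpin: Optional[dict] = None
    trnp_interval: Optional[tuple] = None
    domains: Optional[dict] = None
    newick: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        d = json.loads(text)
        for key in ("anticodon_loop", "trnp_interval"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimulationParams:
    seed: int = 0
    # tree: "fixture", a Newick string, or an int tip count for a random tree
    tree: object = 8
    # explicit planted events [(character, branch, to_state)], or None to
    # draw `events_per_character` random events per character
    events: Optional[list] = None
    events_per_character: int = 1
    event_probability: Optional[float] = None   # per-branch per-character
    # control-region layout
    cr_style: str = "chamaeleonid"   # chamaeleonid | brookesia | plain
    motif_defs: tuple = DEFAULT_MOTIFS
    include_motifs: tuple = ("ETAS1", "ETAS2", "BoxF", "BoxC", "BoxD", "CSB1", "CSB3")
    tandem_unit_len: int = 64
    tandem_copies: int = 8
    tandem_noise: float = 0.02
    include_tandem: bool = True
    at_block_profile: tuple = ((5, 4),) * 5
    at_dinucleotide_copies: int = 15
    include_trnp: bool = True
    trnp_spacer_range: Tuple[int, int] = (200, 400)
    background_gc: float = 0.5
    spacer_len_range: Tuple[int, int] = (25, 60)

    def __post_init__(self):
        for p in (self.tandem_noise, self.background_gc):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.event_probability is not None and not 0 <= self.event_probability <= 1:
            raise ValueError("event_probability out of [0,1]")
        for v in (self.tandem_unit_len, self.tandem_copies):
            if v <= 0:
                raise ValueError("lengths/counts must be positive")

    def asdict(self) -> dict:
        d = dataclasses.asdict(self)
        d["motif_defs"] = [m.name for m in self.motif_defs]
        d["tree"] = str(self.tree)
        return d


# ---------------------------------------------------------------------------
# gene orders on a tree


def order_from_states(states: Dict[str, str]) -> GeneOrder:
    """The linearized gene order implied by a full character-state vector.

    Starts from the canonical vertebrate order and applies, as required by
    the states: the IQM->QIM tRNA swap; tRNA-Pro inversion in place or
    translocation to the 3' side of the CR; duplication of the CR between
    ND5 and ND6 (copies suffixed CR-1/CR-2 in genome order).  C4/C5 do not
    alter the order.
    """
    elems = list(canonical_vertebrate_order().elements)

    if states.get("C1") == "QIM":
        i_pos = [k for k, (n, _) in enumerate(elems) if n == "I"][0]
        q = elems.pop([k for k, (n, _) in enumerate(elems) if n == "Q"][0])
        elems.insert(i_pos, q)

    c2 = states.get("C2", "typical")
    if c2 == "inverted":
        p_pos = [k for k, (n, _) in enumerate(elems) if n == "P"][0]
        elems[p_pos] = ("P", "+")
    elif c2 == "translocated_3prime_CR":
        p = elems.pop([k for k, (n, _) in enumerate(elems) if n == "P"][0])
        cr_pos = max(k for k, (n, _) in enumerate(elems) if n.startswith("CR"))
        elems.insert(cr_pos + 1, p)

    if states.get("C3") == "duplicate_ND5_ND6":
        nd5 = [k for k, (n, _) in enumerate(elems) if n == "ND5"][0]
        elems.insert(nd5 + 1, ("CR-1", "+"))
        for k, (n, o) in enumerate(elems):
            if n == "CR":
                elems[k] = ("CR-2", o)
    return GeneOrder(elements=tuple(elems), anchor="F")


def random_rooted_tree(n_tips: int, rng: random.Random) -> str:
    """Random rooted binary topology over tips t1..tn (Newick, labelled
    internal nodes n1..)."""
    nodes = [f"t{i + 1}" for i in range(n_tips)]
    counter = 0
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        counter += 1
        nodes.append(f"({a},{b})n{counter}")
    return nodes[0] + ";"


def _resolve_tree(params: "SimulationParams", rng: random.Random):
    if params.tree == "fixture":
        from .fixture import FIG3_NEWICK
        return read_tree(FIG3_NEWICK)
    if isinstance(params.tree, int):
        return read_tree(random_rooted_tree(params.tree, rng))
    return read_tree(params.tree)


def simulate_arrangements(params: SimulationParams):
    """Evolve gene orders along a tree by planted discrete events.

    Every lineage starts at the canonical order (all characters in their
    ancestral state).  Events are applied on branches root-to-tip; two
    events for the same character on the same branch raise.  Returns
    ``(tip_orders, matrix, manifest)``: tip orders keyed by taxon, the
    implied :class:`CharacterMatrix`, and the truth manifest.
    """
    rng = random.Random(params.seed)
    tree = _resolve_tree(params, rng)
    branches = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            name = branch_name(node)
            if name in branches:
                raise ValueError(f"duplicate branch name {name!r} in tree")
            branches[name] = node

    seen = set()
    events_by_branch: Dict[str, list] = {}
    if params.events is not None:
        for cid, branch, to_state in (tuple(e) for e in params.events):
            if cid not in CHARACTERS:
                raise ValueError(f"unknown character {cid!r}")
            if branch not in branches:
                raise ValueError(f"unknown branch {branch!r}")
            if to_state not in CHARACTERS[cid].states:
                raise ValueError(f"{cid}: unknown state {to_state!r}")
            if (cid, branch) in seen:
                raise ValueError(
                    f"conflicting events for {cid} on branch {branch!r}")
            seen.add((cid, branch))
            events_by_branch.setdefault(branch, []).append((cid, to_state))
    else:
        # random mode: choose branches now, derived states during the
        # root-to-tip pass so every event changes the inherited state
        names = sorted(branches)
        chosen_branches: Dict[str, set] = {}
        for cid in CHARACTERS:
            if params.event_probability is not None:
                chosen = {b for b in names
                          if rng.random() < params.event_probability}
            else:
                k = min(params.events_per_character, len(names))
                chosen = set(rng.sample(names, k)) if k else set()
            chosen_branches[cid] = chosen
        for name in names:
            hits = [(cid, None) for cid in CHARACTERS
                    if name in chosen_branches[cid]]
            if hits:
                events_by_branch[name] = hits

    ancestral = {cid: c.ancestral_state for cid, c in CHARACTERS.items()}
    node_states = {tree.seed_node: dict(ancestral)}
    manifest_events = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        states = dict(node_states[node.parent_node])
        for cid, to_state in events_by_branch.get(branch_name(node), []):
            frm = states[cid]
            if to_state is None:      # random mode: any state change works
                to_state = rng.choice([s for s in CHARACTERS[cid].states
                                       if s != frm])
            if frm == to_state:
                raise ValueError(
                    f"event {cid} on {branch_name(node)!r} does not change "
                    f"the state ({frm!r})")
            manifest_events.append({"character": cid, "branch": branch_name(node),
                                    "from": frm, "to": to_state})
            states[cid] = to_state
        node_states[node] = states

    tip_orders = {}
    tip_states = {}
    for leaf in tree.leaf_node_iter():
        taxon = leaf.taxon.label
        states = node_states[leaf]
        tip_orders[taxon] = order_from_states(states)
        tip_states[taxon] = dict(states)

    matrix = CharacterMatrix(taxa=sorted(tip_states),
                             states={t: dict(s) for t, s in tip_states.items()})
    manifest = TruthManifest(
        seed=params.seed, params=params.asdict(), events=manifest_events,
        tip_states=tip_states,
        newick=tree.as_string(schema="newick", suppress_rooting=True,
                              unquoted_underscores=True).strip())
    return tip_orders, matrix, manifest


# ---------------------------------------------------------------------------
# sequences


def _random_seq(rng: random.Random, n: int, gc: float = 0.5) -> str:
    g = gc / 2.0
    a = (1.0 - gc) / 2.0
    return "".join(rng.choices("ACGT", weights=[a, g, g, a], k=n))


def _guard(rng: random.Random) -> str:
    """A single base that breaks AT-array periodicity at a boundary."""
    return rng.choice("GC")


def _instantiate_motif(motif: MotifDef, rng: random.Random) -> str:
    return "".join(rng.choice(IUPAC[c]) for c in motif.pattern)


def _mutate(seq: str, rate: float, rng: random.Random) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def simulate_cr(params: SimulationParams):
    """Build one synthetic control region with planted structure.

    Layout (5'->3'): Domain 1 = optional tandem-repeat array then ETAS
    motifs; Domain 2 = Boxes F, C, D in random background; Domain 3 = CSB
    motifs, AT-rich arrays and an optional embedded tRNA-Pro placed a
    configured spacer distance (default 200-400 bp) from the 3' end.
    Chamaeleonid style plants an (A_x T_y)n block array 5' of tRNA-Pro and
    an (AT)n array 3' of it; Brookesia style plants (AT)n on both sides;
    plain style plants no AT arrays.  Returns ``(sequence, manifest)``.
    """
    rng = random.Random(params.seed)
    motif_by_name = {m.name: m for m in params.motif_defs}
    parts: List[str] = []
    pos = 0
    manifest = TruthManifest(seed=params.seed, params=params.asdict())

    def emit(s: str) -> int:
        nonlocal pos
        parts.append(s)
        start = pos + 1
        pos += len(s)
        return start

    def bg():
        emit(_random_seq(rng, rng.randint(*params.spacer_len_range),
                         params.background_gc))

    def emit_motif(name: str):
        if name not in params.include_motifs or name not in motif_by_name:
            return
        s = _instantiate_motif(motif_by_name[name], rng)
        start = emit(s)
        manifest.motifs.append({"name": name, "start": start,
                                "end": start + len(s) - 1})

    # ---- Domain 1
    if params.include_tandem:
        unit = _random_seq(rng, params.tandem_unit_len, params.background_gc)
        array = _mutate(unit * params.tandem_copies, params.tandem_noise, rng)
        start = emit(array)
        manifest.repeats.append({
            "kind": "tandem", "start": start, "end": start + len(array) - 1,
            "unit": unit, "period": params.tandem_unit_len,
            "copies": params.tandem_copies})
        bg()
    emit_motif("ETAS1")
    bg()
    emit_motif("ETAS2")
    d1_end = pos

    # ---- Domain 2
    bg()
    emit_motif("BoxF")
    bg()
    emit_motif("BoxC")
    bg()
    emit_motif("BoxD")
    d2_end = pos

    # ---- Domain 3
    bg()
    emit_motif("CSB1")
    bg()
    emit_motif("CSB2")
    bg()
    emit_motif("CSB3")
    bg()

    def emit_at_block():
        s = "".join("A" * x + "T" * y for x, y in params.at_block_profile)
        emit(_guard(rng))
        start = emit(s)
        emit(_guard(rng))
        manifest.repeats.append({
            "kind": "AT_block", "start": start, "end": start + len(s) - 1,
            "profile": [list(p) for p in params.at_block_profile],
            "copies": len(params.at_block_profile)})

    def emit_at_din():
        s = "AT" * params.at_dinucleotide_copies
        emit(_guard(rng))
        start = emit(s)
        emit(_guard(rng))
        manifest.repeats.append({
            "kind": "AT_dinucleotide", "start": start,
            "end": start + len(s) - 1,
            "copies": params.at_dinucleotide_copies})

    five_prime_kind = {"chamaeleonid": "block", "brookesia": "din",
                       "plain": None}.get(params.cr_style)
    if params.cr_style not in ("chamaeleonid", "brookesia", "plain"):
        raise ValueError(f"unknown cr_style {params.cr_style!r}")

    if five_prime_kind == "block":
        emit_at_block()
    elif five_prime_kind == "din":
        emit_at_din()

    if params.include_trnp:
        bg()
        trnp_seq, _ = simulate_trna("TGG", rng.randrange(2 ** 31))
        start = emit(trnp_seq)
        manifest.trnp_interval = (start, start + len(trnp_seq) - 1)
        spacer = rng.randint(*params.trnp_spacer_range)
        if params.cr_style in ("chamaeleonid", "brookesia"):
            at_len = 2 * params.at_dinucleotide_copies + 2
            lead = max(10, (spacer - at_len) // 2)
            emit(_random_seq(rng, lead, params.background_gc))
            emit_at_din()
            tail = max(0, spacer - at_len - lead)
            emit(_random_seq(rng, tail, params.background_gc))
        else:
            emit(_random_seq(rng, spacer, params.background_gc))
    else:
        bg()

    seq = "".join(parts)
    manifest.domains = {"domain1": [1, d1_end], "domain2": [d1_end + 1, d2_end],
                        "domain3": [d2_end + 1, len(seq)]}
    return seq, manifest


_AA3 = {"F": "Phe", "V": "Val", "I": "Ile", "Q": "Gln", "M": "Met",
        "W": "Trp", "A": "Ala", "N": "Asn", "C": "Cys", "Y": "Tyr",
        "D": "Asp", "K": "Lys", "G": "Gly", "R": "Arg", "H": "His",
        "E": "Glu", "T": "Thr", "P": "Pro", "L": "Leu", "S": "Ser"}


def _genbank_name(symbol: str) -> Tuple[str, Optional[str]]:
    """(feature type, gene qualifier) GenBank spelling for a vocabulary symbol."""
    from .genome import base_symbol, feature_class_of
    base = base_symbol(symbol)
    cls = feature_class_of(base)
    if base == "CR":
        return "D-loop", None
    if base == "OL":
        return "rep_origin", None
    if cls == "protein":
        return "CDS", base
    if cls == "rRNA":
        return "rRNA", f"{base} ribosomal RNA"
    if base.startswith(("L(", "S(")):
        return "tRNA", f"tRNA-{_AA3[base[0]]}({base[2:-1]})"
    return "tRNA", f"tRNA-{_AA3[base]}"


def emit_genbank(order: GeneOrder, path, taxon: str = "synthetic",
                 spans: Optional[Dict[str, int]] = None) -> None:
    """Write a gene order as a synthetic GenBank flat file.

    Features are laid out back-to-back with nominal spans over an all-N
    sequence; gene/product qualifiers use conventional GenBank spellings so
    the record round-trips through the GenBank reader's synonym table.
    """
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO
    from .fixture import _NOMINAL_SPAN
    from .genome import base_symbol

    spans = spans or _NOMINAL_SPAN
    features = []
    pos = 0
    for name, orient in order.elements:
        span = spans.get(base_symbol(name), 70)
        ftype, gene = _genbank_name(name)
        quals = {}
        if gene is not None:
            quals = {"gene": [gene], "product": [gene]}
        features.append(SeqFeature(
            FeatureLocation(pos, pos + span, strand=1 if orient == "+" else -1),
            type=ftype, qualifiers=quals))
        pos += span
    rec = SeqRecord(Seq("N" * pos), id=taxon, name=taxon[:16],
                    description=f"synthetic mitogenome for {taxon}",
                    annotations={"molecule_type": "DNA", "topology": "circular"})
    rec.features = [SeqFeature(FeatureLocation(0, pos), type="source")] + features
    SeqIO.write(rec, path, "genbank")


def simulate_trna(anticodon: str, seed: int, max_tries: int = 100):
    """A cloverleaf-consistent tRNA gene with the given planted anticodon.

    Stems are sampled and closed with exact Watson-Crick complements; the
    anticodon occupies positions 3-5 of the 7-nt anticodon loop.  The draw
    is rejected (and reseeded deterministically) until
    :func:`extract_anticodon` recovers the planted triplet, so the closed
    loop generator->analyzer is exact by construction.
    """
    anticodon = anticodon.upper().replace("U", "T")
    if len(anticodon) != 3 or set(anticodon) - set("ACGT"):
        raise ValueError(f"invalid anticodon triplet {anticodon!r}")
    for attempt in range(max_tries):
        rng = random.Random(seed * 1000 + attempt)

        def stem(n):
            arm = _random_seq(rng, n)
            return arm, _revcomp(arm)

        acc5, acc3 = stem(7)
        d5, d3 = stem(4)
        ac5, ac3 = stem(5)
        t5, t3 = stem(5)
        loop_pad = _random_seq(rng, 2), _random_seq(rng, 2)
        seq = (acc5 + _random_seq(rng, 2)
               + d5 + _random_seq(rng, 8) + d3 + _random_seq(rng, 1)
               + ac5 + loop_pad[0] + anticodon + loop_pad[1] + ac3
               + _random_seq(rng, 4)
               + t5 + _random_seq(rng, 7) + t3
               + acc3 + "A")
        call = extract_anticodon(seq)
        if call.determined and call.anticodon == anticodon:
            ac_start = len(acc5) + 2 + 4 + 8 + 4 + 1 + len(ac5) + 2
            manifest = TruthManifest(
                seed=seed, params={"attempt": attempt},
                anticodon=anticodon,
                anticodon_loop=(ac_start + 1, ac_start + 3))
            return seq, manifest
    raise RuntimeError(f"could not build a clean tRNA in {max_tries} tries")


def simulate_wancy(with_hairpin: bool, seed: int, length: int = 120,
                   stem: int = 8, loop: int = 5, min_stem_guard: int = 6,
                   max_tries: int = 200):
    """A WANCY-cluster spacer with or without a planted OL stem-loop.

    With a hairpin: a perfect `stem`-bp stem enclosing a `loop`-nt loop is
    planted mid-sequence, with non-pairing guard bases flanking it so the
    planted stem is exactly `stem` long.  Without: draws are rejected until
    no hairpin of stem >= `min_stem_guard` exists anywhere.
    """
    for attempt in range(max_tries):
        rng = random.Random(seed * 1000 + attempt + (7919 if with_hairpin else 0))
        if with_hairpin:
            arm = _random_seq(rng, stem)
            loop_seq = _random_seq(rng, loop)
            while pairs(loop_seq[0], loop_seq[-1]):   # no inward stem extension
                loop_seq = _random_seq(rng, loop)
            hp = arm + loop_seq + _revcomp(arm)
            flank = (length - len(hp) - 2) // 2
            left = _random_seq(rng, max(flank, 5))
            right = _random_seq(rng, max(length - len(hp) - 2 - len(left), 5))
            # C guards flank the stem: C does not pair with C, so the
            # planted stem cannot extend outward
            seq = left + "C" + hp + "C" + right
            call = detect_ol_hairpin(seq, min_stem=min(stem, min_stem_guard))
            if call.present and call.stem_length == stem \
                    and call.stem_start == len(left) + 2:
                manifest = TruthManifest(
                    seed=seed, params={"attempt": attempt, "length": length},
                    hairpin={"stem_start": len(left) + 2,
                             "stem_length": stem, "loop_length": loop})
                return seq, manifest
        else:
            seq = _random_seq(rng, length)
            if not detect_ol_hairpin(seq, min_stem=min_stem_guard).present:
                manifest = TruthManifest(
                    seed=seed, params={"attempt": attempt, "length": length},
                    hairpin=None)
                return seq, manifest
    raise RuntimeError(f"could not build WANCY region in {max_tries} tries")
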