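"""Forward simulator of DGR retrohoming with a ground-truth record.

Emits a linear phage-like genome containing the canonical dual-target
cassette layout — reverse transcriptase gene, accessory (Avd) gene, a
non-coding template repeat, a target gene with its variable repeat in the
5' third and (optionally) a second target with the VR in its 3' third. Each
VR is derived from the TR by the adenine-substitution model: every TR
adenine mutates independently with probability ``p_sub`` to a base drawn
from ``base_weights``, and non-adenine positions mutate at a low background
rate ``q_background``. The returned truth record pins every interval and
substitution so detection and profiling are testable end to end.

Model choices that mirror natural cassettes: TR adenines sit predominantly
in AAC/AAT (Asn) codon pairs in the target reading frame; the TR 3' end
(adjacent to the IMH* segment) is adenine-poor; homology between TR and VR
terminates exactly at the declared repeat boundary (the flanking bases
mismatch — otherwise the true repeat would, by definition, be longer).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .genome_io import GenomeRecord, Interval, OrfRecord, translate

STOPS = ("TAA", "TAG", "TGA")
NON_A = "CGT"
BASES = "ACGT"
#: codons with a single adenine at position 2 and a pyrimidine at position 3;
#: no adenine substitution can turn these into a stop codon
LONE_A_CODONS = ("CAC", "CAT", "GAC", "GAT", "TAC", "TAT")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOPS
)


@dataclass
class SimulationParams:
    """Tunable conditions of one simulated retrohoming event per VR."""

    tr_length_bp: int = 120
    n_adenine_pairs: int = 12  # AAC/AAT codons in the TR (2 adenines each)
    n_lone_adenines: int = 1  # isolated adenines outside codon pairs
    p_sub: float = 0.5  # per-adenine substitution probability
    base_weights: dict = field(default_factory=lambda: {"C": 1 / 3, "G": 1 / 3, "T": 1 / 3})
    base_weights_by_position: dict | None = None  # codon position (1|2|3) -> weights
    q_background: float = 0.0  # per-site B->B substitution probability
    dual_target: bool = True
    forbid_stop: bool = True
    genome_length: int = 30000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_sub <= 1 and 0 <= self.q_background <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        for w in [self.base_weights, *(self.base_weights_by_position or {}).values()]:
            if set(w) - set("CGT") or abs(sum(w.values()) - 1) > 1e-9:
                raise ValueError("base weights must cover {C,G,T} and sum to 1")
        if self.tr_length_bp // 3 < self.n_adenine_pairs + self.n_lone_adenines + 6:
            raise ValueError("TR too short for the requested adenine layout")
        if not (60 <= self.tr_length_bp <= 300) or self.tr_length_bp % 3:
            raise ValueError("tr_length_bp must be a multiple of 3 in [60, 300]")
        if not (8000 <= self.genome_length <= 50000):
            raise ValueError("genome_length must lie in [8000, 50000]")

    @property
    def n_adenines(self) -> int:
        return 2 * self.n_adenine_pairs + self.n_lone_adenines


PRESETS = {
    # 25 TR adenines, as in the nd4-like cassettes
    "nd4like": dict(tr_length_bp=120, n_adenine_pairs=12, n_lone_adenines=1),
    # 28 TR adenines, as in the nd12-like cassettes
    "nd12like": dict(tr_length_bp=135, n_adenine_pairs=13, n_lone_adenines=2),
}


@dataclass
class TargetTruth:
    name: str
    vr: Interval
    frame_offset: int
    vr_seq: str
    a_substitutions: list  # (position in TR, TR base, VR base)
    b_substitutions: list
    aa_substitutions: list  # (codon index, aa in TR frame, aa in VR)


@dataclass
class SimulationTruth:
    genome_id: str
    tr: Interval
    tr_seq: str
    targets: list
    orfs: dict  # name -> (start, end, strand)

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "tr": [self.tr.start, self.tr.end],
            "tr_seq": self.tr_seq,
            "orfs": {k: list(v) for k, v in self.orfs.items()},
            "targets": [
                {
                    "name": t.name,
                    "vr": [t.vr.start, t.vr.end],
                    "frame_offset": t.frame_offset,
                    "vr_seq": t.vr_seq,
                    "a_substitutions": [list(x) for x in t.a_substitutions],
                    "b_substitutions": [list(x) for x in t.b_substitutions],
                    "aa_substitutions": [list(x) for x in t.aa_substitutions],
                }
                for t in self.targets
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _rand_seq(rng, n: int, alphabet: str = BASES) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _rand_cds(rng, n_codons: int) -> str:
    """Random stop-free coding sequence: ATG + body + stop."""
    body = "".join(
        _NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), n_codons - 2)
    )
    return "ATG" + body + STOPS[rng.integers(0, 3)]


def build_tr(params: SimulationParams, rng) -> str:
    """Construct a template repeat in the target reading frame.

    Adenines are laid out as ``n_adenine_pairs`` AAC/AAT codons plus
    ``n_lone_adenines`` single-adenine codons among adenine-free spacer
    codons; the first codon and the last five codons (the segment adjacent
    to IMH*) are adenine-free, which also guarantees an adenine-free 12-mer
    for seeding detection.
    """
    n_codons = params.tr_length_bp // 3
    remainder = params.tr_length_bp % 3
    free_slots = list(range(1, n_codons - 5))
    rng.shuffle(free_slots)
    pair_slots = set(free_slots[: params.n_adenine_pairs])
    lone_slots = set(
        free_slots[params.n_adenine_pairs : params.n_adenine_pairs + params.n_lone_adenines]
    )
    codons = []
    for c in range(n_codons):
        if c in pair_slots:
            codons.append("AAC" if rng.random() < 0.5 else "AAT")
        elif c in lone_slots:
            codons.append(LONE_A_CODONS[rng.integers(0, len(LONE_A_CODONS))])
        else:
            codons.append(_rand_seq(rng, 3, NON_A))
    return "".join(codons) + _rand_seq(rng, remainder, NON_A)


def _draw_base(rng, weights: dict) -> str:
    bases = sorted(weights)
    probs = np.array([weights[b] for b in bases])
    return bases[rng.choice(len(bases), p=probs / probs.sum())]


def mutate_tr(tr: str, params: SimulationParams, rng):
    """Apply the adenine model to a TR copy; returns (vr, a_subs, b_subs).

    Stop-codon avoidance (``forbid_stop``) resamples the substituted bases
    of any codon that would read as a stop in the target frame, up to 100
    attempts, then falls back to the first stop-free base choice.
    """
    vr = list(tr)
    a_subs, b_subs = [], []
    for p, base in enumerate(tr):
        if base == "A":
            if rng.random() < params.p_sub:
                weights = params.base_weights
                if params.base_weights_by_position:
                    weights = params.base_weights_by_position.get(p % 3 + 1, weights)
                vr[p] = _draw_base(rng, weights)
                a_subs.append(p)
        elif rng.random() < params.q_background:
            alternatives = [b for b in BASES if b != base]
            vr[p] = alternatives[rng.integers(0, 3)]
            b_subs.append(p)

    if params.forbid_stop:
        changed = set(a_subs) | set(b_subs)
        for c in range(len(tr) // 3):
            lo = 3 * c
            mutable = [p for p in range(lo, lo + 3) if p in changed]
            attempts = 0
            while "".join(vr[lo : lo + 3]) in STOPS and mutable and attempts < 100:
                for p in mutable:
                    if tr[p] == "A":
                        weights = params.base_weights
                        if params.base_weights_by_position:
                            weights = params.base_weights_by_position.get(p % 3 + 1, weights)
                        vr[p] = _draw_base(rng, weights)
                    else:
                        alternatives = [b for b in BASES if b != tr[p]]
                        vr[p] = alternatives[rng.integers(0, 3)]
                attempts += 1
            if "".join(vr[lo : lo + 3]) in STOPS and mutable:
                for p in mutable:  # deterministic fallback: first stop-free base
                    pool = NON_A if tr[p] == "A" else [b for b in BASES if b != tr[p]]
                    for b in pool:
                        vr[p] = b
                        if "".join(vr[lo : lo + 3]) not in STOPS:
                            break
                    if "".join(vr[lo : lo + 3]) not in STOPS:
                        break
    vr = "".join(vr)
    a_records = [(p, tr[p], vr[p]) for p in sorted(a_subs) if vr[p] != tr[p]]
    b_records = [(p, tr[p], vr[p]) for p in sorted(b_subs) if vr[p] != tr[p]]
    return vr, a_records, b_records


def _aa_substitutions(tr: str, vr: str) -> list:
    subs = []
    for c in range(len(tr) // 3):
        aa_t = translate(tr[3 * c : 3 * c + 3])
        aa_v = translate(vr[3 * c : 3 * c + 3])
        if aa_t != aa_v:
            subs.append((c, aa_t, aa_v))
    return subs


def _divergent_flank(rng, tr_flank: str) -> str:
    """Adenine-free segment mismatching the TR flank base-for-base.

    Used for the two codons on each side of an embedded VR: homology between
    TR and VR terminates, by definition, at the declared repeat boundary, so
    the simulator delimits each boundary with a short divergent segment.
    All-non-A whole codons can never read as stops.
    """
    out = []
    for b in tr_flank:
        pool = [x for x in NON_A if x != b]
        out.append(pool[rng.integers(0, len(pool))])
    return "".join(out)


def _target_gene(rng, vr: str, tr_flanks: tuple[str, str], vr_at_codon: int, total_codons: int):
    """Assemble a target CDS embedding the VR at a codon boundary.

    ``tr_flanks`` are the 6 bp segments flanking the TR in the genome; the
    two codons on each side of the VR are forced to mismatch them so the
    repeat boundary is sharp. ``total_codons`` includes start and stop.
    """
    left6, right6 = tr_flanks
    vr_codons = len(vr) // 3
    pre = vr_at_codon - 2  # codons before the divergent pair, incl. ATG
    post = total_codons - vr_at_codon - vr_codons - 3
    assert pre >= 1 and post >= 1
    before = _divergent_flank(rng, left6)
    after = _divergent_flank(rng, right6)
    head = _rand_cds(rng, pre + 1)[:-3]  # ATG + pre-1 codons, stop removed
    tail = "".join(
        _NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), post)
    ) + STOPS[rng.integers(0, 3)]
    cds = head + before + vr + after + tail
    vr_offset = len(head) + 6  # VR start within the CDS
    assert len(cds) == total_codons * 3
    return cds, vr_offset


def simulate_genome(params: SimulationParams):
    """Emit (GenomeRecord, ORF annotation, SimulationTruth) for one genome.

    Deterministic given ``params.seed``. Layout on the forward strand:
    filler, RT gene, Avd gene, TR (non-coding, flanked by mismatch-forcing
    bases), target1 (VR in the 5' third), target2 (VR in the 3' third,
    dual-target only), filler.
    """
    rng = np.random.default_rng(params.seed)
    gid = f"sim_{params.seed}"
    tr = build_tr(params, rng)
    tr_codons = len(tr) // 3

    rt_cds = _rand_cds(rng, 300)
    avd_cds = _rand_cds(rng, 130)
    tr_left = _rand_seq(rng, 6, NON_A)
    tr_right = _rand_seq(rng, 6, NON_A)

    # target1 ~570 codons with VR in the 5' third; target2 smaller with the
    # VR ending a few codons before the stop (3' third)
    total1 = max(570, 3 * (30 + tr_codons // 2) + 30)
    targets_spec = [("target1", 30, total1)]
    if params.dual_target:
        total2 = tr_codons + 260
        targets_spec.append(("target2", total2 - tr_codons - 8, total2))

    target_parts = []
    for name, vr_at, total in targets_spec:
        vr, a_recs, b_recs = mutate_tr(tr, params, rng)
        cds, vr_off = _target_gene(rng, vr, (tr_left, tr_right), vr_at, total)
        target_parts.append((name, cds, vr_off, vr, a_recs, b_recs))

    fillers = [int(rng.integers(1200, 2000)) for _ in range(5)]
    parts = []
    cursor = 0
    coords = {}

    def add(seq: str, name: str | None = None):
        nonlocal cursor
        if name:
            coords[name] = (cursor, cursor + len(seq))
        parts.append(seq)
        cursor += len(seq)

    add(_rand_seq(rng, fillers[0]))
    add(rt_cds, "rt")
    add(_rand_seq(rng, fillers[1]))
    add(avd_cds, "avd")
    add(_rand_seq(rng, fillers[2]))
    add(tr_left)
    add(tr, "tr")
    add(tr_right)
    vr_coords = {}
    for i, (name, cds, vr_off, *_rest) in enumerate(target_parts):
        add(_rand_seq(rng, fillers[3 + i]))
        add(cds, name)
        vr_coords[name] = (coords[name][0] + vr_off, coords[name][0] + vr_off + len(tr))
    pad = params.genome_length - cursor
    if pad < 0:
        raise ValueError("genome_length too small for the cassette layout")
    add(_rand_seq(rng, pad))

    genome = GenomeRecord(id=gid, seq="".join(parts), source="dgrscan simulator")

    orfs = []
    labels = {
        "rt": "reverse transcriptase",
        "avd": "accessory variability determinant (Avd)",
        "target1": "tentaclin-like target protein 1",
        "target2": "target protein 2",
    }
    for name in ("rt", "avd", *(t[0] for t in target_parts)):
        s, e = coords[name]
        orfs.append(
            OrfRecord(
                genome_id=gid,
                start=s,
                end=e,
                strand="+",
                protein=translate(genome.seq[s:e])[:-1],
                label=labels[name],
            )
        )

    truth_targets = []
    for name, _cds, _off, vr, a_recs, b_recs in target_parts:
        s, e = vr_coords[name]
        truth_targets.append(
            TargetTruth(
                name=name,
                vr=Interval(s, e),
                frame_offset=0,
                vr_seq=vr,
                a_substitutions=a_recs,
                b_substitutions=b_recs,
                aa_substitutions=_aa_substitutions(tr[: 3 * tr_codons], vr[: 3 * tr_codons]),
            )
        )
    truth = SimulationTruth(
        genome_id=gid,
        tr=Interval(*coords["tr"]),
        tr_seq=tr,
        targets=truth_targets,
        orfs={k: (*coords[k], "+") for k in coords if k != "tr"},
    )
    return genome, orfs, truth


@dataclass
class SpectrumExpectation:
    """Closed-form moments of the per-VR substitution counts."""

    n_adenines: int
    mean_A_sub: float
    var_A_sub: float
    n_non_adenines: int
    mean_B_sub: float
    var_B_sub: float


def expected_spectrum(params: SimulationParams) -> SpectrumExpectation:
    """Binomial expectation/variance of n_A_sub and n_B_sub per VR.

    Every covered TR adenine mutates independently with probability
    ``p_sub`` (substituted bases are drawn from {C,G,T}, so a substitution
    always changes the base), and each non-adenine site mutates with
    probability ``q_background``.
    """
    nA = params.n_adenines
    nB = params.tr_length_bp - nA
    p, q = params.p_sub, params.q_background
    return SpectrumExpectation(
        n_adenines=nA,
        mean_A_sub=nA * p,
        var_A_sub=nA * p * (1 - p),
        n_non_adenines=nB,
        mean_B_sub=nB * q,
        var_B_sub=nB * q * (1 - q),
    )
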