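"""TR/VR repeat-pair detection and DGR cassette assembly.

Diversity-generating retroelements copy a non-coding template repeat (TR)
into one or more variable repeats (VR) inside target genes, substituting
only adenine positions. The scanner below exploits that asymmetry: exact
adenine-free k-mers seed candidate pairs (an adenine-free stretch of the
template survives retrohoming unchanged), seeds are extended without gaps
under a scoring model that forgives mismatches at adenine columns, and the
template copy is designated as the one carrying adenine in (nearly) all
mismatched columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .genome_io import GenomeRecord, Interval, OrfRecord, revcomp

MATCH = 1
MISMATCH = -2  # mismatch where neither copy has A (background B->B)


@dataclass
class RepeatPair:
    """An aligned TR/VR candidate pair (ungapped, equal-length intervals)."""

    genome_id: str
    tr: Interval
    vr: Interval
    n_columns: int
    n_match: int
    n_A_sub: int  # columns with TR=A, VR != A
    n_B_sub: int  # columns with TR in {C,G,T}, VR differs
    n_ambiguous: int = 0
    orientation: str = "direct"
    score: int = 0

    def __post_init__(self) -> None:
        assert self.n_match + self.n_A_sub + self.n_B_sub + self.n_ambiguous == self.n_columns
        assert self.tr.overlap(self.vr) == 0, "TR and VR intervals overlap"


@dataclass
class CassetteTarget:
    vr: Interval
    target_orf: OrfRecord | None
    vr_position_class: str  # five_prime / three_prime / internal
    frame_offset: int | None
    n_A_sub: int = 0
    n_B_sub: int = 0


@dataclass
class DgrCassette:
    genome_id: str
    rt_orf: OrfRecord | None
    avd_orf: OrfRecord | None
    tr: Interval
    targets: list[CassetteTarget] = field(default_factory=list)


def _column_score(a: str, b: str) -> int:
    if a == b:
        return MATCH
    if "N" in (a, b) or "A" in (a, b):
        return 0
    return MISMATCH


def _extend_seed(sa: str, sb: str, i: int, j: int, k: int, xdrop: int, max_ext: int):
    """Ungapped X-drop extension of an exact seed sa[i:i+k] == sb[j:j+k].

    Returns column offsets [lo, hi) relative to i/j spanning the maximal
    scoring extension (earliest argmax, so score-neutral adenine columns at
    the boundary are not absorbed).
    """
    score = k * MATCH
    best, hi = score, k
    t = k
    limit = min(len(sa) - i, len(sb) - j, k + max_ext)
    while t < limit:
        score += _column_score(sa[i + t], sb[j + t])
        if score > best:
            best, hi = score, t + 1
        elif score < best - xdrop:
            break
        t += 1
    score, lo = best, 0
    cur = best
    t = -1
    limit = -min(i, j, max_ext)
    while t >= limit:
        cur += _column_score(sa[i + t], sb[j + t])
        if cur > score:
            score, lo = cur, t
        elif cur < score - xdrop:
            break
        t -= 1
    return lo, hi, score


def _classify_copies(sa_span: str, sb_span: str):
    n_match = n_amb = a_in_1 = a_in_2 = both_a = 0
    for a, b in zip(sa_span, sb_span):
        if a == b:
            n_match += 1
        elif "N" in (a, b):
            n_amb += 1
        else:
            if a == "A":
                a_in_1 += 1
            if b == "A":
                a_in_2 += 1
            if a == b == "A":  # unreachable (a != b) but keeps intent clear
                both_a += 1
    n_mm = len(sa_span) - n_match - n_amb
    return n_match, n_amb, n_mm, a_in_1, a_in_2


def find_repeat_pairs(
    genome: GenomeRecord,
    min_len: int = 100,
    max_len: int = 150,
    max_B_sub_frac: float = 0.1,
    min_A_sub: int = 3,
    k: int = 12,
    xdrop: int = 20,
    tr_designation_frac: float = 0.8,
    scan_inverted: bool = True,
    max_seed_occ: int = 50,
) -> list[RepeatPair]:
    """Scan a genome for TR/VR repeat pairs under the adenine-asymmetric model.

    Seeds are exact adenine-free ``k``-mers shared by two loci; extension is
    ungapped (match +1, mismatch at an adenine column 0, other mismatch −2)
    with X-drop termination. A pair is reported when the extended length lies
    in ``[min_len, max_len]``, the background-mismatch fraction is at most
    ``max_B_sub_frac``, at least ``min_A_sub`` adenine substitutions are
    present, and one copy carries adenine in at least ``tr_designation_frac``
    of the mismatched columns (that copy is designated TR). Both strands are
    scanned; inverted pairs compare the forward sequence against its reverse
    complement. Overlapping reports are merged keeping the highest score.
    """
    if not (50 <= min_len <= max_len <= 300):
        raise ValueError("require 50 <= min_len <= max_len <= 300")
    L = genome.length
    if L < min_len * 2:
        return []
    overhang = max_len + 50 if genome.topology == "circular" else 0
    seq = genome.seq + genome.seq[:overhang]
    rseq = revcomp(seq)
    Lx = len(seq)

    def plus_iv(p: int, length: int, strand: str) -> Interval | None:
        # map an interval in extended-plus coordinates back to the genome
        s = p % L if p >= L else p
        e = s + length
        if e > L:
            if genome.topology == "circular":
                return None  # origin-spanning repeat: not representable
            e = min(e, L)
        return Interval(s, e, strand)

    candidates: list[RepeatPair] = []

    def scan(sa: str, sb: str, self_mode: bool, mapper) -> None:
        index: dict[str, list[int]] = {}
        for p in range(len(sb) - k + 1):
            w = sb[p : p + k]
            if "A" in w or "N" in w:
                continue
            index.setdefault(w, []).append(p)
        seen_diag: dict[int, list[tuple[int, int]]] = {}
        for i in range(len(sa) - k + 1):
            w = sa[i : i + k]
            if "A" in w or "N" in w:
                continue
            hits = index.get(w)
            if not hits or len(hits) > max_seed_occ:
                continue
            for j in hits:
                if self_mode and j <= i:
                    continue
                d = j - i
                covered = seen_diag.setdefault(d, [])
                if any(lo <= i < hi for lo, hi in covered):
                    continue
                lo, hi, score = _extend_seed(sa, sb, i, j, k, xdrop, max_len)
                covered.append((i + lo, i + hi))
                length = hi - lo
                if not (min_len <= length <= max_len):
                    continue
                span1 = sa[i + lo : i + hi]
                span2 = sb[j + lo : j + hi]
                n_match, n_amb, n_mm, a1, a2 = _classify_copies(span1, span2)
                if n_mm == 0:
                    tr_first, n_A, n_B = True, 0, 0
                else:
                    f1, f2 = a1 / n_mm, a2 / n_mm
                    if max(f1, f2) < tr_designation_frac:
                        continue
                    tr_first = f1 >= f2
                    n_A = a1 if tr_first else a2
                    n_B = n_mm - n_A
                if n_A < min_A_sub or n_B / length > max_B_sub_frac:
                    continue
                ivs = mapper(i + lo, j + lo, length)
                if ivs is None:
                    continue
                iv1, iv2 = ivs
                tr_iv, vr_iv = (iv1, iv2) if tr_first else (iv2, iv1)
                if tr_iv.overlap(vr_iv):
                    continue
                candidates.append(
                    RepeatPair(
                        genome_id=genome.id,
                        tr=tr_iv,
                        vr=vr_iv,
                        n_columns=length,
                        n_match=n_match,
                        n_A_sub=n_A,
                        n_B_sub=n_B,
                        n_ambiguous=n_amb,
                        orientation="inverted" if iv1.strand != iv2.strand else "direct",
                        score=score,
                    )
                )

    def map_plus(p1, p2, length):
        a = plus_iv(p1, length, "+")
        b = plus_iv(p2, length, "+")
        return None if a is None or b is None else (a, b)

    def map_minus(p1, p2, length):
        # positions are in revcomp(extended) coordinates
        a = plus_iv(Lx - (p1 + length), length, "-")
        b = plus_iv(Lx - (p2 + length), length, "-")
        return None if a is None or b is None else (a, b)

    def map_inverted(p1, p2, length):
        a = plus_iv(p1, length, "+")
        b = plus_iv(Lx - (p2 + length), length, "-")
        return None if a is None or b is None else (a, b)

    scan(seq, seq, True, map_plus)
    scan(rseq, rseq, True, map_minus)
    if scan_inverted:
        scan(seq, rseq, False, map_inverted)

    # merge overlapping reports, highest score first; '+' preferred on ties
    candidates.sort(key=lambda p: (-p.score, p.tr.strand, p.tr.start, p.vr.start))
    kept: list[RepeatPair] = []
    for cand in candidates:
        cpair = {(cand.tr.start, cand.tr.end), (cand.vr.start, cand.vr.end)}
        redundant = False
        for prev in kept:
            ivs = [prev.tr, prev.vr]
            ok = 0
            for s, e in cpair:
                iv = Interval(s, e)
                if any(iv.reciprocal_overlap(p) >= 0.9 for p in ivs):
                    ok += 1
            if ok == 2:
                redundant = True
                break
        if not redundant:
            kept.append(cand)
    kept.sort(key=lambda p: (p.tr.start, p.vr.start))
    return kept


def _gene_relative_position(vr: Interval, orf: OrfRecord) -> float:
    """Fractional position of the VR midpoint along the gene, 5'->3'."""
    if orf.strand == "+":
        return (vr.midpoint - orf.start) / len(orf)
    return (orf.end - vr.midpoint) / len(orf)


def classify_vr_position(vr: Interval, orf: OrfRecord) -> str:
    rel = _gene_relative_position(vr, orf)
    if rel <= 1 / 3:
        return "five_prime"
    if rel >= 2 / 3:
        return "three_prime"
    return "internal"


def vr_frame_offset(vr: Interval, orf: OrfRecord) -> int:
    """Phase of the VR start relative to the target ORF codon grid."""
    if orf.strand == "+":
        return (vr.start - orf.start) % 3
    return (orf.end - vr.end) % 3


def _interval_distance(a: Interval, b: Interval) -> int:
    if a.overlap(b):
        return 0
    return max(a.start, b.start) - min(a.end, b.end)


def _nearest_labeled_orf(orfs, tr: Interval, needles, window_bp: int):
    best, best_d = None, window_bp + 1
    for orf in orfs:
        label = orf.label.lower()
        if any(n in label for n in needles):
            d = _interval_distance(orf.interval, tr)
            if d < best_d:
                best, best_d = orf, d
    return best


def assemble_cassettes(
    genome: GenomeRecord,
    pairs: list[RepeatPair],
    orfs: list[OrfRecord],
    window_bp: int = 5000,
) -> list[DgrCassette]:
    """Group repeat pairs sharing a TR into cassettes and attach ORF context.

    Pairs whose TR intervals overlap reciprocally by at least 90% form one
    cassette with multiple targets. Each VR's target ORF is the ORF fully
    containing it (longest wins); the RT gene is the nearest ORF labeled
    "reverse transcriptase" within ``window_bp`` of the TR, the accessory
    gene the nearest labeled Avd/accessory ORF.
    """
    groups: list[list[RepeatPair]] = []
    for pair in sorted(pairs, key=lambda p: (p.tr.start, p.vr.start)):
        for grp in groups:
            if grp[0].tr.reciprocal_overlap(pair.tr) >= 0.9:
                grp.append(pair)
                break
        else:
            groups.append([pair])

    cassettes = []
    for grp in groups:
        tr = max(grp, key=lambda p: p.score).tr
        targets = []
        for pair in grp:
            containing = [
                o
                for o in orfs
                if o.start <= pair.vr.start and pair.vr.end <= o.end
            ]
            if not containing:
                warnings.warn(
                    f"{genome.id}: VR {pair.vr.start + 1}-{pair.vr.end} not contained "
                    "in any ORF; excluded from amino-acid analysis"
                )
                targets.append(
                    CassetteTarget(pair.vr, None, "internal", None, pair.n_A_sub, pair.n_B_sub)
                )
                continue
            orf = max(containing, key=len)
            targets.append(
                CassetteTarget(
                    vr=pair.vr,
                    target_orf=orf,
                    vr_position_class=classify_vr_position(pair.vr, orf),
                    frame_offset=vr_frame_offset(pair.vr, orf),
                    n_A_sub=pair.n_A_sub,
                    n_B_sub=pair.n_B_sub,
                )
            )
        targets.sort(key=lambda t: t.vr.start)
        cassettes.append(
            DgrCassette(
                genome_id=genome.id,
                rt_orf=_nearest_labeled_orf(orfs, tr, ("reverse transcriptase",), window_bp),
                avd_orf=_nearest_labeled_orf(orfs, tr, ("avd", "accessory"), window_bp),
                tr=tr,
                targets=targets,
            )
        )
    cassettes.sort(key=lambda c: c.tr.start)
    return cassettes


def screen_phage_contigs(
    records: list[GenomeRecord],
    orfs_per_record: dict[str, list[OrfRecord]],
    required_labels: tuple[str, ...] = ("large terminase subunit", "portal protein"),
) -> list[str]:
    """Keep records whose ORF annotation carries all required labels.

    Case-insensitive substring match; mirrors the common pre-filter that a
    bona fide phage contig encodes both the large terminase subunit and the
    portal protein.
    """
    kept = []
    for rec in records:
        labels = [o.label.lower() for o in orfs_per_record.get(rec.id, [])]
        if all(any(req.lower() in lab for lab in labels) for req in required_labels):
            kept.append(rec.id)
    return kept
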