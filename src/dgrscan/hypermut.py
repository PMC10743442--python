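"""Quantifying adenine-specific hypermutation between TR and VR.

The reverse transcriptase of a DGR misincorporates only at adenine positions
of the template repeat RNA, so a TR/VR alignment separates cleanly into
match columns, adenine substitutions (TR=A, VR differs — the DGR signal) and
background substitutions at non-adenine columns (B→B). This module aligns
the two repeats, classifies columns, translates the repeats in the target
gene's frame and reports the substitution spectrum at nucleotide, codon and
amino-acid level, including the codon-position bias of A→C changes within
AAC/AAT (Asn) codons and the set of residues reachable from a codon when
only its adenines may mutate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import NamedTuple

import pandas as pd

from .genome_io import translate

MATCH = 1
MM_AT_TR_A = 0
MM_OTHER = -2
GAP = -4

#: Disjoint amino-acid categories. Histidine is counted as positively
#: charged, not aromatic, to keep the partition disjoint; override via the
#: ``categories`` argument of :func:`substitution_profile` if desired.
AA_CATEGORIES: dict[str, frozenset] = {
    "aromatic": frozenset("FWY"),
    "negative": frozenset("DE"),
    "positive": frozenset("KRH"),
    "cysteine": frozenset("C"),
    "hydrophobic_nonaromatic": frozenset("AVLIMPG"),
    "hydrophilic_uncharged": frozenset("STNQ"),
}


def aa_category(residue: str, categories: dict | None = None) -> str:
    for name, members in (categories or AA_CATEGORIES).items():
        if residue in members:
            return name
    return "other"


@dataclass
class RepeatAlignment:
    """Columnwise TR/VR correspondence with substitution-class labels.

    ``tr_seq``/``vr_seq`` are the aligned strings (equal length, gaps as
    ``-``) covering only the overlapping span; ``tr_span`` locates that span
    within ``tr_source``, the full template sequence. ``tr_frame_offset`` is
    the phase of ``tr_source[0]`` relative to the target ORF codon grid
    (inherited from the VR's placement: the TR itself is non-coding).
    """

    tr_seq: str
    vr_seq: str
    column_class: list[str]
    tr_frame_offset: int = 0
    tr_span: tuple[int, int] = (0, 0)
    tr_source: str = ""

    def __post_init__(self) -> None:
        if not (len(self.tr_seq) == len(self.vr_seq) == len(self.column_class)):
            raise ValueError("aligned sequences and classes must have equal length")
        if self.tr_frame_offset not in (0, 1, 2):
            raise ValueError("tr_frame_offset must be 0, 1 or 2")


class SubstitutionProfile(NamedTuple):
    """Nucleotide/codon/amino-acid substitution summary for one TR/VR pair."""

    n_tr_adenines: int
    n_tr_adenines_covered: int
    n_A_sub: int
    n_B_sub: int
    n_ambiguous: int
    per_position_A_fate: dict  # TR position (in tr_source coords) -> VR base
    aa_substitutions: list  # (codon_index, aa_tr, aa_vr)
    aa_substitutions_adenine_only: list  # subset from codons free of B->B changes
    aa_category_counts: dict
    codon_bias: dict  # (tr_codon, codon_position 1|2, vr_base) -> count


def classify_column(a: str, b: str) -> str:
    if "N" in (a, b) or "-" in (a, b):
        return "ambiguous"
    if a == b:
        return "match"
    if a == "A" and b != "A":
        return "A_sub"
    return "B_sub"


def _score(a: str, b: str) -> int:
    if a == b:
        return MATCH
    return MM_AT_TR_A if a == "A" else MM_OTHER


def _semiglobal_align(tr: str, vr: str):
    """Semi-global DP: the shorter sequence aligned inside the longer.

    Scoring: match +1, mismatch at a TR adenine 0, other mismatch −2, gap −4.
    End gaps in the longer sequence are free. Traceback prefers diagonal
    moves and the leftmost co-optimal placement, so results are
    deterministic. Returns the aligned strings plus the covered span of
    ``tr``.
    """
    n, m = len(tr), len(vr)
    tr_longer = n >= m
    # F[i][j]: best score aligning tr[:i] with vr[:j]
    F = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        F[i][0] = 0 if tr_longer else i * GAP
    for j in range(1, m + 1):
        F[0][j] = j * GAP if tr_longer else 0
    for i in range(1, n + 1):
        a = tr[i - 1]
        Fi, Fp = F[i], F[i - 1]
        for j in range(1, m + 1):
            Fi[j] = max(Fp[j - 1] + _score(a, vr[j - 1]), Fp[j] + GAP, Fi[j - 1] + GAP)
    if tr_longer:
        best_i = max(range(n + 1), key=lambda i: F[i][m])
        i, j = best_i, m
    else:
        best_j = max(range(m + 1), key=lambda j: F[n][j])
        i, j = n, best_j
    out_tr, out_vr = [], []
    while i > 0 and j > 0:
        a, b = tr[i - 1], vr[j - 1]
        if F[i][j] == F[i - 1][j - 1] + _score(a, b):
            out_tr.append(a)
            out_vr.append(b)
            i -= 1
            j -= 1
        elif F[i][j] == F[i - 1][j] + GAP:
            out_tr.append(a)
            out_vr.append("-")
            i -= 1
        else:
            out_tr.append("-")
            out_vr.append(b)
            j -= 1
    # leftover residues of the fully-aligned (shorter) sequence are real,
    # penalized gap columns; leftover residues of the longer sequence are
    # its free end gap and stay outside the alignment span
    if tr_longer:
        while j > 0:
            out_tr.append("-")
            out_vr.append(vr[j - 1])
            j -= 1
    else:
        while i > 0:
            out_tr.append(tr[i - 1])
            out_vr.append("-")
            i -= 1
    tr_lo = i
    tr_hi = best_i if tr_longer else n
    return "".join(reversed(out_tr)), "".join(reversed(out_vr)), tr_lo, tr_hi


def align_tr_vr(tr: str, vr: str, tr_frame_offset: int = 0) -> RepeatAlignment:
    """Align a template repeat to a variable repeat and classify columns.

    Equal-length inputs are paired positionally (the retrohoming product has
    the template's length); otherwise the shorter is placed inside the
    longer by semi-global alignment and columns outside the overlap are
    excluded from the alignment span.
    """
    tr, vr = tr.upper(), vr.upper()
    if not tr or not vr:
        raise ValueError("empty sequence")
    ratio = len(vr) / len(tr)
    if not (0.5 <= ratio <= 2):
        raise ValueError(f"VR/TR length ratio {ratio:.2f} outside [0.5, 2]")
    if len(tr) == len(vr):
        a_tr, a_vr, tr_lo, tr_hi = tr, vr, 0, len(tr)
    else:
        a_tr, a_vr, tr_lo, tr_hi = _semiglobal_align(tr, vr)
    classes = [classify_column(a, b) for a, b in zip(a_tr, a_vr)]
    return RepeatAlignment(
        tr_seq=a_tr,
        vr_seq=a_vr,
        column_class=classes,
        tr_frame_offset=tr_frame_offset,
        tr_span=(tr_lo, tr_hi),
        tr_source=tr,
    )


def count_tr_adenines(tr: str) -> int:
    """Number of adenines in a template repeat (the mutable positions)."""
    return tr.upper().count("A")


def substitution_profile(
    aln: RepeatAlignment, categories: dict | None = None
) -> SubstitutionProfile:
    """Nucleotide, codon and amino-acid substitution spectrum of one pair.

    Amino-acid substitutions are computed over codons fully contained in the
    aligned span, translating TR and VR in the frame the VR occupies in its
    target gene. Codons touching an ambiguous or gap column are skipped.
    Category counts follow the VR residue (the residue the hypermutation
    produced). ``codon_bias`` tallies, for TR codons AAC and AAT, which base
    replaced the adenine at codon positions 1 and 2.
    """
    classes = aln.column_class
    n_A = sum(c == "A_sub" for c in classes)
    n_B = sum(c == "B_sub" for c in classes)
    n_amb = sum(c == "ambiguous" for c in classes)
    n_tr_adenines = count_tr_adenines(aln.tr_source) if aln.tr_source else sum(
        b == "A" for b in aln.tr_seq
    )
    covered = sum(b == "A" for b in aln.tr_seq)

    # map aligned columns back to tr_source coordinates
    per_position: dict[int, str] = {}
    tr_pos = aln.tr_span[0]
    col_tr_pos = []
    for a, b in zip(aln.tr_seq, aln.vr_seq):
        col_tr_pos.append(tr_pos if a != "-" else None)
        if a == "A" and b not in ("-",):
            per_position[tr_pos] = b
        if a != "-":
            tr_pos += 1

    f = aln.tr_frame_offset
    first_codon_start = (3 - f) % 3  # tr_source coord of the first full codon
    aa_subs: list[tuple[int, str, str]] = []
    aa_subs_a_only: list[tuple[int, str, str]] = []
    cat_counts = {name: 0 for name in (categories or AA_CATEGORIES)}
    codon_bias: dict[tuple[str, int, str], int] = {}

    # walk codons over the gap-free aligned span
    if "-" not in aln.tr_seq and "-" not in aln.vr_seq:
        span_start = aln.tr_span[0]
        # first codon boundary at or after span start
        p = span_start + ((first_codon_start - span_start) % 3)
        while p + 3 <= aln.tr_span[1]:
            i = p - span_start
            tr_codon = aln.tr_seq[i : i + 3]
            vr_codon = aln.vr_seq[i : i + 3]
            codon_classes = classes[i : i + 3]
            p += 3
            if "ambiguous" in codon_classes:
                continue
            codon_index = (p - 3 - first_codon_start) // 3
            if tr_codon in ("AAC", "AAT"):
                for cp in (0, 1):
                    if vr_codon[cp] != "A":
                        key = (tr_codon, cp + 1, vr_codon[cp])
                        codon_bias[key] = codon_bias.get(key, 0) + 1
            aa_tr = translate(tr_codon)
            aa_vr = translate(vr_codon)
            if aa_tr != aa_vr:
                aa_subs.append((codon_index, aa_tr, aa_vr))
                cat_counts[aa_category(aa_vr, categories)] = (
                    cat_counts.get(aa_category(aa_vr, categories), 0) + 1
                )
                if "B_sub" not in codon_classes:
                    aa_subs_a_only.append((codon_index, aa_tr, aa_vr))
    elif aln.tr_seq:
        import warnings

        warnings.warn("gapped alignment: amino-acid analysis restricted to empty set")

    return SubstitutionProfile(
        n_tr_adenines=n_tr_adenines,
        n_tr_adenines_covered=covered,
        n_A_sub=n_A,
        n_B_sub=n_B,
        n_ambiguous=n_amb,
        per_position_A_fate=per_position,
        aa_substitutions=aa_subs,
        aa_substitutions_adenine_only=aa_subs_a_only,
        aa_category_counts=cat_counts,
        codon_bias=codon_bias,
    )


class AchievableResidues(NamedTuple):
    residues: frozenset
    stop_reachable: bool

    def __len__(self) -> int:
        return len(self.residues)

    def __contains__(self, item) -> bool:
        return item in self.residues


def achievable_residues(codon: str, table: int = 11) -> AchievableResidues:
    """Residues reachable from a codon when only its adenines may mutate.

    Every adenine position is substituted independently by A/C/G/T while
    non-adenine positions stay fixed; variants are translated (table 11 by
    default). Stop codons are excluded from the residue set but flagged.
    For the Asn codons AAC and AAT this yields 15 residues — every amino
    acid except Gln, Met, Lys, Glu and Trp.
    """
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - set("ACGT"):
        raise ValueError(f"invalid codon {codon!r}")
    choices = ["ACGT" if b == "A" else b for b in codon]
    residues = set()
    stop = False
    for variant in product(*choices):
        aa = translate("".join(variant), table=table)
        if aa == "*":
            stop = True
        else:
            residues.add(aa)
    return AchievableResidues(frozenset(residues), stop)


def codon_position_bias(profiles: list[SubstitutionProfile]) -> pd.DataFrame:
    """Aggregate A→C/G/T counts at codon positions 1 and 2 of AAC/AAT codons.

    Returns a table indexed by (tr_codon, codon_position) with replacement
    base counts plus, per codon, the ratio of position-1 to position-2 A→C
    counts (NaN when both are zero) — the quantity in which natural DGR
    spectra show a strong position-1 preference.
    """
    rows = []
    for tr_codon in ("AAC", "AAT"):
        counts = {}
        for pos in (1, 2):
            for base in "CGT":
                counts[(pos, base)] = sum(
                    p.codon_bias.get((tr_codon, pos, base), 0) for p in profiles
                )
        for pos in (1, 2):
            rows.append(
                {
                    "tr_codon": tr_codon,
                    "codon_position": pos,
                    "A_to_C": counts[(pos, "C")],
                    "A_to_G": counts[(pos, "G")],
                    "A_to_T": counts[(pos, "T")],
                }
            )
    df = pd.DataFrame(rows).set_index(["tr_codon", "codon_position"])
    ratios = []
    for tr_codon in ("AAC", "AAT"):
        p1 = df.loc[(tr_codon, 1), "A_to_C"]
        p2 = df.loc[(tr_codon, 2), "A_to_C"]
        ratios.extend([p1 / p2 if (p1 or p2) and p2 else float("nan")] * 2)
    df["pos1_over_pos2_A_to_C"] = ratios
    return df


@dataclass
class SharedMutationReport:
    """Coincidence of adenine mutations between two VRs of the same TR."""

    pairs: dict  # TR adenine position -> (base in VR1, base in VR2)
    n_positions: int = 0
    n_both_mutated: int = 0
    n_both_same_base: int = 0
    n_only_one_mutated: int = 0
    n_neither_mutated: int = 0


def compare_vr1_vr2(aln1: RepeatAlignment, aln2: RepeatAlignment) -> SharedMutationReport:
    """Compare the adenine fates of two VRs retrohomed from the same TR.

    Independent mutagenesis predicts mostly discordant positions; the report
    counts, over TR adenines covered by both alignments, how often both VRs
    mutated, mutated to the same base, or only one mutated.
    """
    if aln1.tr_source != aln2.tr_source:
        raise ValueError("alignments are not against the same TR sequence")
    p1 = substitution_profile(aln1).per_position_A_fate
    p2 = substitution_profile(aln2).per_position_A_fate
    shared = sorted(set(p1) & set(p2))
    rep = SharedMutationReport(pairs={})
    for pos in shared:
        b1, b2 = p1[pos], p2[pos]
        rep.pairs[pos] = (b1, b2)
        m1, m2 = b1 != "A", b2 != "A"
        if m1 and m2:
            rep.n_both_mutated += 1
            if b1 == b2:
                rep.n_both_same_base += 1
        elif m1 or m2:
            rep.n_only_one_mutated += 1
        else:
            rep.n_neither_mutated += 1
    rep.n_positions = len(shared)
    return rep
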