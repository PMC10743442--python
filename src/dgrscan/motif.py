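"""Conservation profiles and signature scanning for the Cterm-Ig anchor.

Tentaclins — the receptor-binding protein family carrying the hypermutated
C-type-lectin beta-hairpin — share a C-terminal Ig-like anchor domain whose
few invariant residues form the family signature despite otherwise low
sequence identity. This module learns a per-column residue-frequency
profile from a user-supplied alignment of such domains and scans candidate
proteins for the signature within their C-terminal tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AA_ALPHABET + "-"
_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}


@dataclass
class ConservationProfile:
    """Per-column residue frequencies over an aligned domain set."""

    freq: pd.DataFrame  # rows = columns (0-based), cols = 20 residues + gap
    n_sequences: int
    conserved_columns: list  # (column_index, residue) at >= threshold
    threshold: float = 1.0

    @property
    def columns(self) -> int:
        return len(self.freq)


def build_profile(aligned_seqs: list[str], threshold: float = 1.0) -> ConservationProfile:
    """Columnwise residue frequencies and conserved-column calls.

    Requires at least two equal-length sequences over the 20-residue
    alphabet plus gap. A column is conserved when a single residue (gap
    excluded) reaches the threshold frequency; the default 1.0 calls only
    100%-invariant columns, the convention used to define the tentaclin
    Cterm-Ig signature.
    """
    if len(aligned_seqs) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in aligned_seqs}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    ncol = lengths.pop()
    counts = np.zeros((ncol, len(ALPHABET)), dtype=float)
    for seq in aligned_seqs:
        seq = seq.upper()
        for c, res in enumerate(seq):
            if res not in _AA_INDEX:
                raise ValueError(f"invalid residue {res!r} at column {c + 1}")
            counts[c, _AA_INDEX[res]] += 1
    freq = counts / len(aligned_seqs)
    conserved = []
    for c in range(ncol):
        top = int(np.argmax(freq[c, : len(AA_ALPHABET)]))
        if freq[c, top] >= threshold:
            conserved.append((c, AA_ALPHABET[top]))
    return ConservationProfile(
        freq=pd.DataFrame(freq, columns=list(ALPHABET)),
        n_sequences=len(aligned_seqs),
        conserved_columns=conserved,
        threshold=threshold,
    )


@dataclass
class MatchReport:
    protein_id: str
    best_offset: int | None  # offset within the scanned tail, 0-based
    best_score: float | None  # mean per-column log-odds at best offset
    carries_signature: bool
    signature_offset: int | None = None

    def to_dict(self) -> dict:
        return {
            "protein_id": self.protein_id,
            "best_offset": self.best_offset,
            "best_score": self.best_score,
            "carries_signature": self.carries_signature,
            "signature_offset": self.signature_offset,
        }


def scan_protein(
    protein: str,
    profile: ConservationProfile,
    tail_window: int = 100,
    protein_id: str = "",
    background: float | None = None,
    pseudocount: float = 0.01,
) -> MatchReport:
    """Slide the profile (ungapped) over the C-terminal tail of a protein.

    The score at an offset is the mean per-column log-odds of the observed
    residue against a uniform background (1/20 by default). A protein
    carries the signature iff some offset matches *all* conserved columns
    exactly; ``signature_offset`` reports the first such offset. Proteins
    shorter than the profile yield a no-match report rather than an error.
    """
    protein = protein.upper()
    L = profile.columns
    tail = protein[-tail_window:]
    if len(tail) < L or L == 0:
        vacuous = L == 0
        return MatchReport(protein_id, None, None, carries_signature=vacuous)
    bg = background if background is not None else 1 / len(AA_ALPHABET)
    logodds = np.log((profile.freq.to_numpy() + pseudocount) / (1 + pseudocount * len(ALPHABET)) / bg)
    try:
        encoded = np.array([_AA_INDEX[r] for r in tail])
    except KeyError as exc:
        raise ValueError(f"invalid residue in protein {protein_id!r}: {exc}") from exc
    n_off = len(tail) - L + 1
    cols = np.arange(L)
    # score matrix: offsets x columns via stride trick on the encoded tail
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    scores = logodds[cols, windows].mean(axis=1)
    best = int(np.argmax(scores))
    sig_offset = None
    if profile.conserved_columns:
        cons_cols = np.array([c for c, _ in profile.conserved_columns])
        cons_res = np.array([_AA_INDEX[r] for _, r in profile.conserved_columns])
        hits = (windows[:, cons_cols] == cons_res).all(axis=1)
        idx = np.flatnonzero(hits)
        if idx.size:
            sig_offset = int(idx[0])
    else:
        sig_offset = best
    return MatchReport(
        protein_id=protein_id,
        best_offset=best,
        best_score=float(scores[best]),
        carries_signature=sig_offset is not None,
        signature_offset=sig_offset,
    )


def expected_monomorphic_rate(freqs: np.ndarray, n_sequences: int) -> float:
    """Probability a random alignment column of n sequences is monomorphic.

    For residue frequencies ``p_i`` this is ``sum_i p_i ** n`` — the
    analytic false-positive rate for 100%-conservation calls on columns with
    no planted signal.
    """
    return float(np.sum(np.asarray(freqs, dtype=float) ** n_sequences))


def read_aligned_fasta(path) -> tuple[list[str], list[str]]:
    """Read an aligned protein FASTA (gap '-'); returns (ids, sequences)."""
    from Bio import SeqIO

    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return ids, seqs


def profile_to_tsv(profile: ConservationProfile, path) -> None:
    """Write the frequency matrix (logo-tool compatible) with conserved calls."""
    with open(path, "w") as fh:
        fh.write("# column\t" + "\t".join(ALPHABET) + "\tconserved_residue\n")
        conserved = dict(profile.conserved_columns)
        for c in range(profile.columns):
            row = "\t".join(f"{profile.freq.iloc[c][a]:.6g}" for a in ALPHABET)
            fh.write(f"{c + 1}\t{row}\t{conserved.get(c, '.')}\n")
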