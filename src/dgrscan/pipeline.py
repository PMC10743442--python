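"""End-to-end runner and report writers.

Ties detection and hypermutation profiling together and writes the tabular
reports: ``cassettes.tsv`` (one row per TR/VR target), ``profile.tsv``
(per-target substitution counts and amino-acid category spectrum),
``aa.tsv`` (individual amino-acid substitutions) and ``summary.json``.
All user-facing coordinates are 1-based inclusive; TSVs carry a commented
header line.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .detect import DgrCassette, assemble_cassettes, find_repeat_pairs
from .genome_io import GenomeRecord, OrfRecord, read_fasta, read_genbank, revcomp
from .hypermut import AA_CATEGORIES, aa_category, align_tr_vr, substitution_profile

log = logging.getLogger("dgrscan")


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    inputs: list = field(default_factory=list)  # FASTA paths
    genbank: list = field(default_factory=list)  # GenBank paths
    orfs: str | None = None  # ORF annotation TSV
    min_len: int = 100
    max_len: int = 150
    max_B_sub_frac: float = 0.1
    min_A_sub: int = 3
    seed_k: int = 12
    window_bp: int = 5000
    min_orf_aa: int = 50
    genetic_code: int = 11
    conservation_threshold: float = 1.0
    outdir: str = "dgr_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (50 <= self.min_len <= self.max_len <= 300):
            raise ValueError("require 50 <= min_len <= max_len <= 300")
        if not (0 <= self.max_B_sub_frac <= 1):
            raise ValueError("max_B_sub_frac must lie in [0, 1]")
        if not (0 < self.conservation_threshold <= 1):
            raise ValueError("conservation_threshold must lie in (0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = yaml.safe_dump(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def write_tsv(path, columns: list[str], rows: list[tuple]) -> None:
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_orf_tsv(path, orfs: list[OrfRecord]) -> None:
    write_tsv(
        path,
        ["genome_id", "start", "end", "strand", "label", "protein"],
        [(o.genome_id, o.start + 1, o.end, o.strand, o.label, o.protein) for o in orfs],
    )


def read_orf_tsv(path) -> list[OrfRecord]:
    orfs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gid, start, end, strand, label, protein = (line.split("\t") + [""] * 6)[:6]
            orfs.append(
                OrfRecord(
                    genome_id=gid,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    protein=protein,
                    label=label,
                )
            )
    return orfs


def _oriented(seq: str, strand: str) -> str:
    return revcomp(seq) if strand == "-" else seq


def analyze_cassette(genome: GenomeRecord, cassette: DgrCassette):
    """Substitution profiles for every target of a cassette.

    The TR and each VR are read in the orientation of the VR's target gene
    and aligned positionally (equal lengths) or semi-globally; the TR
    translation frame is inherited from the VR's placement in the ORF.
    Targets whose VR is not contained in any ORF are skipped.
    """
    results = []
    tr_plus = genome.seq[cassette.tr.start : cassette.tr.end]
    for idx, target in enumerate(cassette.targets, start=1):
        if target.target_orf is None or target.frame_offset is None:
            results.append((idx, target, None, None))
            continue
        strand = target.target_orf.strand
        tr_seq = _oriented(tr_plus, "-" if cassette.tr.strand != strand else "+")
        vr_seq = _oriented(genome.seq[target.vr.start : target.vr.end], strand)
        aln = align_tr_vr(tr_seq, vr_seq, tr_frame_offset=target.frame_offset)
        results.append((idx, target, aln, substitution_profile(aln)))
    return results


def run_pipeline(config: RunConfig) -> dict:
    """Run detect + profile over all configured genomes; write reports.

    Returns the summary dictionary that is also written to
    ``summary.json``. Deterministic: re-running an identical configuration
    on identical inputs reproduces every output byte for byte.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("dgrscan %s | config %s | seed %d", __version__, config.digest(), config.seed)

    genomes: list[GenomeRecord] = []
    orfs_by_genome: dict[str, list[OrfRecord]] = {}
    for path in config.inputs:
        genomes.extend(read_fasta(path))
    for path in config.genbank:
        genome, orfs = read_genbank(path)
        genomes.append(genome)
        orfs_by_genome.setdefault(genome.id, []).extend(orfs)
    if config.orfs:
        for orf in read_orf_tsv(config.orfs):
            orfs_by_genome.setdefault(orf.genome_id, []).append(orf)

    from .genome_io import find_orfs

    cass_rows, prof_rows, aa_rows = [], [], []
    summary: dict = {
        "version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "genomes": {},
    }
    cat_names = list(AA_CATEGORIES)
    for genome in genomes:
        orfs = orfs_by_genome.get(genome.id)
        if orfs is None:
            orfs = find_orfs(genome, config.min_orf_aa)
        pairs = find_repeat_pairs(
            genome,
            min_len=config.min_len,
            max_len=config.max_len,
            max_B_sub_frac=config.max_B_sub_frac,
            min_A_sub=config.min_A_sub,
            k=config.seed_k,
        )
        cassettes = assemble_cassettes(genome, pairs, orfs, window_bp=config.window_bp)
        gsum = {"n_cassettes": len(cassettes), "cassettes": []}
        for cassette in cassettes:
            csum = {
                "tr": [cassette.tr.start + 1, cassette.tr.end],
                "rt_gene": cassette.rt_orf.label if cassette.rt_orf else "unassigned",
                "tr_adenines": genome.seq[cassette.tr.start : cassette.tr.end].count("A"),
                "targets": [],
            }
            for idx, target, aln, prof in analyze_cassette(genome, cassette):
                orf_label = target.target_orf.label if target.target_orf else "none"
                cass_rows.append(
                    (
                        genome.id,
                        cassette.tr.start + 1,
                        cassette.tr.end,
                        target.vr.start + 1,
                        target.vr.end,
                        target.vr.strand,
                        orf_label,
                        target.vr_position_class,
                        target.frame_offset if target.frame_offset is not None else ".",
                        target.n_A_sub,
                        target.n_B_sub,
                    )
                )
                tsum = {
                    "vr": [target.vr.start + 1, target.vr.end],
                    "position_class": target.vr_position_class,
                    "target_gene": orf_label,
                    "n_A_sub": target.n_A_sub,
                    "n_B_sub": target.n_B_sub,
                }
                if prof is not None:
                    prof_rows.append(
                        (
                            genome.id,
                            idx,
                            prof.n_tr_adenines,
                            prof.n_tr_adenines_covered,
                            prof.n_A_sub,
                            prof.n_B_sub,
                            len(prof.aa_substitutions),
                            len(prof.aa_substitutions_adenine_only),
                            *(prof.aa_category_counts.get(c, 0) for c in cat_names),
                        )
                    )
                    for codon_index, aa_tr, aa_vr in prof.aa_substitutions:
                        span = aln.tr_span[0]
                        first = (3 - aln.tr_frame_offset) % 3
                        cstart = first + 3 * codon_index
                        aa_rows.append(
                            (
                                genome.id,
                                idx,
                                codon_index + 1,
                                aln.tr_source[cstart : cstart + 3],
                                _codon_in_vr(aln, cstart),
                                aa_tr,
                                aa_vr,
                                aa_category(aa_vr),
                            )
                        )
                    tsum.update(
                        covered_adenines=prof.n_tr_adenines_covered,
                        n_aa_sub=len(prof.aa_substitutions),
                        n_aa_sub_adenine_only=len(prof.aa_substitutions_adenine_only),
                        aa_categories=prof.aa_category_counts,
                    )
                csum["targets"].append(tsum)
            gsum["cassettes"].append(csum)
        summary["genomes"][genome.id] = gsum

    write_tsv(
        outdir / "cassettes.tsv",
        [
            "genome_id",
            "tr_start",
            "tr_end",
            "vr_start",
            "vr_end",
            "strand",
            "target_orf",
            "vr_position_class",
            "frame_offset",
            "n_A_sub",
            "n_B_sub",
        ],
        cass_rows,
    )
    write_tsv(
        outdir / "profile.tsv",
        [
            "genome_id",
            "target_index",
            "n_tr_adenines",
            "n_tr_adenines_covered",
            "n_A_sub",
            "n_B_sub",
            "n_aa_sub",
            "n_aa_sub_adenine_only",
            *cat_names,
        ],
        prof_rows,
    )
    write_tsv(
        outdir / "aa.tsv",
        [
            "genome_id",
            "target_index",
            "codon_index",
            "tr_codon",
            "vr_codon",
            "aa_tr",
            "aa_vr",
            "category_vr",
        ],
        aa_rows,
    )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _codon_in_vr(aln, cstart: int) -> str:
    """The VR bases aligned to the TR codon starting at tr_source[cstart]."""
    offset = cstart - aln.tr_span[0]
    if "-" in aln.tr_seq or "-" in aln.vr_seq:
        return "..."
    return aln.vr_seq[offset : offset + 3]
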