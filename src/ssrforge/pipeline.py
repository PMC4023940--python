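"""End-to-end pipeline orchestration.

Runs the marker-development stages in their natural order —

    qc -> decontam -> [external re-assembly hook] -> asm_stats -> scan
       -> primers -> diversity

— from a single :class:`RunConfig`, writing every stage's outputs plus a
run manifest with record counts and output checksums. Re-running with an
identical config and inputs reproduces identical checksums (timestamps
are recorded outside the checksummed payload). Record-count conservation
(kept + removed = input) is asserted at every boundary.

Re-assembly after read purging is an external hook: when
``assembler_cmd`` is set it is executed as a shell command template with
``{reads1} {reads2} {out_fasta}`` placeholders; otherwise the
decontaminated contig set passes through unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import subprocess
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import assembly_qc, decontamination, popgen, primer_design, read_qc, ssr_scan

logger = logging.getLogger(__name__)

ALL_STAGES = ["qc", "decontam", "asm_stats", "scan", "primers", "diversity"]


@dataclass
class RunConfig:
    """Single source of truth for a pipeline run.

    Defaults reproduce the standard stringent-filtering recipe: drop a
    pair when >10% of a mate's bases fall below Q20 or >10% are N; flag
    contaminant contigs at depth >50x and shred them into 87-mers; keep
    contigs of at least 500 bp; SSR thresholds 10/6/5/5/5/5 repeats for
    motif sizes 1-6.
    """

    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # inputs
    reads1: str | None = None
    reads2: str | None = None
    contigs_fasta: str | None = None
    depth_tsv: str | None = None
    contaminant_refs_fasta: str | None = None
    genepop: str | None = None
    outdir: str = "ssrforge_out"
    # read QC
    adapters: list[str] = field(default_factory=list)
    q_threshold: int = 20
    low_q_frac: float = 0.10
    n_frac: float = 0.10
    min_len_after_trim: int = 36
    # decontamination
    depth_threshold: float = 50.0
    k: int = 87
    screen_k: int = 31
    containment: float = 0.5
    assembler_cmd: str | None = None
    # assembly / SSR / primers
    min_contig_len: int = 500
    min_repeats: dict = field(default_factory=lambda: dict(ssr_scan.MIN_REPEATS_DEFAULT))
    min_flank: int = 200
    # popgen
    he_unbiased: bool = True
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.min_repeats = {int(k): int(v) for k, v in cfg.min_repeats.items()}
        bad = [s for s in cfg.stages if s not in ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        return cfg


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)
    version: str = ""

    def record(self, stage: str, counts: dict, outputs: dict[str, str]) -> None:
        self.stages[stage] = {"counts": counts, "outputs": outputs}
        self.timestamps[stage] = time.time()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "config": self.config,
                    "stages": self.stages,
                    "timestamps": self.timestamps,
                },
                fh,
                indent=2,
                default=str,
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in order; halt (with a partial manifest
    already on disk) if a stage raises."""
    from . import __version__

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), version=__version__)
    manifest_path = out / "manifest.json"

    pairs = None
    contigs = None

    def _load_contigs():
        depths = (
            assembly_qc.read_depth_tsv(config.depth_tsv) if config.depth_tsv else None
        )
        return assembly_qc.read_fasta(config.contigs_fasta, depths)

    try:
        if "qc" in config.stages:
            if not (config.reads1 and config.reads2):
                raise ValueError("qc stage requires reads1 and reads2")
            raw = list(read_qc.read_fastq_pairs(config.reads1, config.reads2))
            pairs = read_qc.filter_pairs(
                raw,
                adapters=config.adapters,
                q_threshold=config.q_threshold,
                low_q_frac=config.low_q_frac,
                n_frac=config.n_frac,
                min_len_after_trim=config.min_len_after_trim,
            )
            assert len(pairs) <= len(raw)
            report = read_qc.qc_summary(len(raw), pairs)
            p1, p2 = out / "clean_R1.fastq", out / "clean_R2.fastq"
            read_qc.write_fastq_pairs(pairs, p1, p2)
            rp = out / "qc_report.json"
            rp.write_text(report.to_json())
            manifest.record(
                "qc",
                {"raw_pairs": len(raw), "clean_pairs": len(pairs)},
                {str(p): _sha256(p) for p in (p1, p2, rp)},
            )

        if "decontam" in config.stages:
            if contigs is None:
                if not config.contigs_fasta:
                    raise ValueError("decontam stage requires contigs_fasta")
                contigs = _load_contigs()
            if pairs is None and config.reads1 and config.reads2:
                pairs = list(read_qc.read_fastq_pairs(config.reads1, config.reads2))
            refs = (
                assembly_qc.read_fasta(config.contaminant_refs_fasta)
                if config.contaminant_refs_fasta
                else []
            )
            n_in = len(pairs or [])
            clean_pairs, survivors, report = decontamination.decontaminate(
                contigs,
                pairs or [],
                refs,
                depth_threshold=config.depth_threshold,
                k=config.k,
                screen_k=config.screen_k,
                containment_threshold=config.containment,
            )
            assert report.reads_kept + report.reads_removed == n_in
            p1, p2 = out / "purged_R1.fastq", out / "purged_R2.fastq"
            read_qc.write_fastq_pairs(clean_pairs, p1, p2)
            fa = out / "decontaminated_contigs.fasta"
            if config.assembler_cmd:
                cmd = config.assembler_cmd.format(reads1=p1, reads2=p2, out_fasta=fa)
                logger.info("re-assembly hook: %s", cmd)
                subprocess.run(cmd, shell=True, check=True)
                contigs = assembly_qc.read_fasta(fa)
            else:
                assembly_qc.write_fasta(survivors, fa)
                contigs = survivors
            rp = out / "purge_report.json"
            rp.write_text(json.dumps(dataclasses.asdict(report), indent=2))
            pairs = clean_pairs
            manifest.record(
                "decontam",
                {
                    "pairs_in": n_in,
                    "pairs_kept": report.reads_kept,
                    "pairs_removed": report.reads_removed,
                    "contigs_flagged_by_depth": len(report.contigs_flagged_by_depth),
                    "contigs_flagged_by_reference": len(report.contigs_flagged_by_reference),
                    "contigs_kept": len(contigs),
                },
                {str(p): _sha256(p) for p in (p1, p2, fa, rp)},
            )

        if "asm_stats" in config.stages:
            if contigs is None:
                contigs = _load_contigs()
            n_in = len(contigs)
            contigs = assembly_qc.length_filter(contigs, config.min_contig_len)
            report = assembly_qc.base_composition(contigs)
            rp = out / "assembly_report.json"
            rp.write_text(report.to_json())
            manifest.record(
                "asm_stats",
                {
                    "contigs_in": n_in,
                    "contigs_kept": len(contigs),
                    "total_length": report.total_length,
                    "n50": report.n50,
                    "n90": report.n90,
                },
                {str(rp): _sha256(rp)},
            )

        loci = None
        if "scan" in config.stages:
            if contigs is None:
                contigs = _load_contigs()
                contigs = assembly_qc.length_filter(contigs, config.min_contig_len)
            loci = ssr_scan.scan_contigs(contigs, config.min_repeats)
            tsv = out / "ssr_loci.tsv"
            ssr_scan.loci_to_tsv(loci, tsv)
            summary = ssr_scan.summarize(loci)
            sp = out / "ssr_summary.json"
            sp.write_text(
                json.dumps(
                    {
                        "total": summary.total,
                        "by_motif_size": dict(summary.by_motif_size),
                        "by_canonical": dict(summary.by_canonical),
                    },
                    indent=2,
                )
            )
            manifest.record(
                "scan",
                {"ssrs_found": len(loci)},
                {str(p): _sha256(p) for p in (tsv, sp)},
            )

        if "primers" in config.stages:
            if contigs is None:
                contigs = _load_contigs()
                contigs = assembly_qc.length_filter(contigs, config.min_contig_len)
            if loci is None:
                loci = ssr_scan.scan_contigs(contigs, config.min_repeats)
            candidates = ssr_scan.select_marker_candidates(loci, contigs, config.min_flank)
            designed, failures = primer_design.design_for_loci(candidates, contigs)
            assert len(designed) + len(failures) == len(candidates)
            tsv = out / "primers.tsv"
            primer_design.primers_to_tsv(designed, tsv)
            manifest.record(
                "primers",
                {
                    "loci_in": len(loci),
                    "candidates": len(candidates),
                    "pairs_designed": len(designed),
                    "design_failures": len(failures),
                },
                {str(tsv): _sha256(tsv)},
            )

        if "diversity" in config.stages:
            if not config.genepop:
                raise ValueError("diversity stage requires a genepop input")
            table = popgen.read_genepop(config.genepop)
            stats = popgen.diversity_table(table, unbiased=config.he_unbiased)
            tsv = out / "diversity.tsv"
            with open(tsv, "w") as fh:
                fh.write("locus\tna\the\tho\tshannon_i\tn\n")
                for s in stats:
                    fh.write(
                        f"{s.locus}\t{s.na}\t{s.he:.4f}\t{s.ho:.4f}\t"
                        f"{s.shannon_i:.4f}\t{s.n}\n"
                    )
            outputs = {str(tsv): _sha256(tsv)}
            counts = {"populations": len(table.populations), "loci": len(table.loci)}
            if len(table.populations) >= 3:
                dm = popgen.nei_distance_matrix(table)
                phy = out / "nei_distances.phy"
                popgen.write_phylip(dm, phy)
                tree = popgen.neighbor_joining(dm)
                nwk = out / "nj_tree.nwk"
                nwk.write_text(popgen.to_newick(tree) + "\n")
                outputs.update({str(p): _sha256(p) for p in (phy, nwk)})
            manifest.record("diversity", counts, outputs)
    finally:
        manifest.write(manifest_path)
    return manifest
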