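"""End-to-end pipeline driver: simulate -> call -> resample -> burden -> repeats.

A run is described by a :class:`PipelineConfig` (round-trippable through
YAML). Every random stage receives a seed derived deterministically from the
global seed and a stage label, so a config plus seed reproduces the whole
run byte-for-byte; the :class:`RunManifest` records output checksums to make
that verifiable.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .alignments import AlignmentSet
from .burden import BurdenConfig, compare_callsets, filter_rare_large
from .caller import SVCallSet, call_svs
from .events import LogUniformSizeModel, plant_sv_events
from .genome import ReferenceGenome, generate_reference
from .io import read_fai, read_vcf, write_bed, write_bedgraph, write_vcf
from .repeats import compare_to_null, permuted_breakpoint_null, scan_callset
from .resample import ReadLibrary, match_libraries, subset_alignments
from .simulate import ErrorModel, ReadLengthModel, simulate_alignments

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, label: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    mix = np.random.SeedSequence(
        [int(global_seed) % (2**31), zlib.crc32(label.encode())]
    )
    return int(mix.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Nested per-stage parameters for one reproducible run."""

    mode: str = "synthetic"  # {"synthetic", "sam", "vcf"}
    seed: int = 0
    out_dir: str = "raresv_run"
    # synthetic mode
    chrom_lengths: tuple[int, ...] = (1_000_000, 1_000_000)
    n_nuclei: int = 5_000
    coverage: float = 30.0
    control_rates: dict = field(
        default_factory=lambda: {"DEL": 1.0, "DUP": 1.0, "INS": 1.0, "INV": 1.0}
    )
    treatment_multipliers: dict = field(
        default_factory=lambda: {"DEL": 2.0, "DUP": 3.0}
    )
    size_model: dict = field(
        default_factory=lambda: {"min_len": 1_000, "max_len": 100_000}
    )
    ins_size_model: dict | None = None
    read_model: dict = field(
        default_factory=lambda: {"mean_log": 9.0, "sd_log": 0.5, "min_length": 500}
    )
    error_model: dict = field(
        default_factory=lambda: {"small_indel_rate": 5e-5, "small_indel_max_len": 50}
    )
    # external inputs (sam / vcf modes)
    treat_path: str | None = None
    ctrl_path: str | None = None
    ref_fasta: str | None = None
    genome_fai: str | None = None
    post_call_keep: float = 1.0
    # caller
    min_signature_len: int = 30
    merge_gap: int = 100
    position_window: int = 500
    size_ratio_min: float = 0.7
    min_mapq: int = 0
    # resampling
    n_length_bins: int = 20
    # burden
    burden: dict = field(default_factory=dict)
    # repeats
    flank_len: int = 200
    max_microhomology: int = 25

    def burden_config(self) -> BurdenConfig:
        return BurdenConfig(**self.burden)

    def size_models(self) -> dict:
        base = LogUniformSizeModel(**self.size_model)
        models = {"default": base}
        if self.ins_size_model:
            models["INS"] = LogUniformSizeModel(**self.ins_size_model)
        return models

    def treatment_rates(self) -> dict:
        rates = dict(self.control_rates)
        for t, m in self.treatment_multipliers.items():
            rates[t] = rates.get(t, 0.0) * m
        return rates

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["chrom_lengths"] = list(self.chrom_lengths)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "chrom_lengths" in data:
            data["chrom_lengths"] = tuple(data["chrom_lengths"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunManifest:
    config: dict
    config_hash: str
    version: str
    stages: list[str]
    checksums: dict[str, str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _simulate_arm(cfg: PipelineConfig, rates: dict, label: str,
                  ref: ReferenceGenome) -> AlignmentSet:
    table = plant_sv_events(
        ref, rates, cfg.size_models(), cfg.n_nuclei,
        seed=stage_seed(cfg.seed, f"plant:{label}"),
    )
    return simulate_alignments(
        ref, table, cfg.coverage,
        ReadLengthModel(**{"family": "lognormal", **cfg.read_model}),
        ErrorModel(**cfg.error_model),
        seed=stage_seed(cfg.seed, f"reads:{label}"),
        label=label,
    )


def _post_call_subsample(cs: SVCallSet, keep: float, seed: int) -> SVCallSet:
    """Subsample supporting reads of an existing callset (vcf-mode stand-in
    for read-level resampling); calls losing all support are dropped."""
    if keep >= 1.0:
        return cs
    rng = np.random.default_rng(seed)
    out = []
    for c in cs.calls:
        kept = frozenset(r for r in sorted(c.supporting_reads)
                         if rng.random() < keep)
        if kept:
            out.append(
                type(c)(c.sv_type, c.chrom, c.start, c.end, c.svlen,
                        len(kept), kept, c.mate_chrom, c.mate_pos)
            )
    return SVCallSet(out, dict(cs.provenance, post_call_keep=keep))


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute the configured pipeline and write all artifacts.

    Stage order (synthetic mode): reference -> plant+simulate both arms ->
    read-level resampling -> SV calling -> burden comparison -> breakpoint
    repeat scan -> manifest. ``sam`` mode starts at resampling; ``vcf`` mode
    starts at the burden comparison (with optional post-call support
    subsampling).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    artifacts: dict[str, Path] = {}
    bcfg = cfg.burden_config()
    ref: ReferenceGenome | None = None

    def run_stage(name, fn):
        try:
            result = fn()
        except Exception as exc:  # annotate the failing stage
            (out / "failed").write_text(f"{name}: {exc}\n")
            raise StageFailure(name, exc) from exc
        stages.append(name)
        return result

    if cfg.mode == "synthetic":
        def gen():
            g = generate_reference(
                cfg.chrom_lengths, stage_seed(cfg.seed, "reference")
            )
            g.to_fasta(out / "reference.fa")
            g.to_fai(out / "reference.fa.fai")
            artifacts["reference.fa"] = out / "reference.fa"
            return g
        ref = run_stage("reference", gen)
        chrom_lengths = ref.chrom_lengths()

        def sim():
            treat = _simulate_arm(cfg, cfg.treatment_rates(), "treat", ref)
            ctrl = _simulate_arm(cfg, cfg.control_rates, "ctrl", ref)
            for arm in (treat, ctrl):
                path = out / f"{arm.label}.sam"
                arm.to_sam(path)
                artifacts[path.name] = path
                arm.truth.table.to_tsv(out / f"{arm.label}.truth.tsv")
                artifacts[f"{arm.label}.truth.tsv"] = out / f"{arm.label}.truth.tsv"
            return treat, ctrl
        aln_treat, aln_ctrl = run_stage("simulate", sim)
    elif cfg.mode == "sam":
        def load():
            t = AlignmentSet.from_sam(cfg.treat_path, "treat")
            c = AlignmentSet.from_sam(cfg.ctrl_path, "ctrl")
            return t, c
        aln_treat, aln_ctrl = run_stage("load_sam", load)
        chrom_lengths = dict(aln_treat.chrom_lengths)
        if cfg.ref_fasta:
            ref = ReferenceGenome.from_fasta(cfg.ref_fasta)
    elif cfg.mode == "vcf":
        aln_treat = aln_ctrl = None
        if cfg.ref_fasta:
            ref = ReferenceGenome.from_fasta(cfg.ref_fasta)
    else:
        raise ValueError(f"unknown mode {cfg.mode!r}")

    if cfg.mode in ("synthetic", "sam"):
        def resample():
            libT = ReadLibrary.from_alignments(aln_treat)
            libC = ReadLibrary.from_alignments(aln_ctrl)
            libT2, libC2, report = match_libraries(
                libT, libC, None, seed=stage_seed(cfg.seed, "resample")
            )
            report.to_tsv(out / "resample_report.tsv")
            artifacts["resample_report.tsv"] = out / "resample_report.tsv"
            for lib in (libT2, libC2):
                p = out / f"{lib.label}.kept_reads.txt"
                p.write_text("".join(f"{r}\n" for r in lib.read_ids))
                artifacts[p.name] = p
            return (
                subset_alignments(aln_treat, libT2),
                subset_alignments(aln_ctrl, libC2),
                report,
            )
        aln_treat, aln_ctrl, _ = run_stage("resample", resample)

        def call():
            sets = []
            for arm in (aln_treat, aln_ctrl):
                cs = call_svs(
                    arm,
                    cfg.min_signature_len, cfg.merge_gap,
                    cfg.position_window, cfg.size_ratio_min, cfg.min_mapq,
                )
                p = out / f"{arm.label}.calls.vcf"
                write_vcf(cs, chrom_lengths, p)
                artifacts[p.name] = p
                sets.append(cs)
            return sets
        cs_treat, cs_ctrl = run_stage("call", call)
    else:  # vcf mode
        def load_vcf():
            t, cl_t = read_vcf(cfg.treat_path, "treat")
            c, cl_c = read_vcf(cfg.ctrl_path, "ctrl")
            cl = cl_t or cl_c
            if cfg.genome_fai:
                cl = read_fai(cfg.genome_fai)
            if not cl or any(v is None for v in cl.values()):
                raise ValueError(
                    "vcf mode needs contig lengths (VCF ##contig or --genome FAI)"
                )
            keep = cfg.post_call_keep
            t = _post_call_subsample(t, keep, stage_seed(cfg.seed, "postcall:t"))
            c = _post_call_subsample(c, keep, stage_seed(cfg.seed, "postcall:c"))
            return t, c, cl
        cs_treat, cs_ctrl, chrom_lengths = run_stage("load_vcf", load_vcf)

    def burden_stage():
        report = compare_callsets(
            cs_treat, cs_ctrl, chrom_lengths, bcfg,
            metadata={
                "config_hash": cfg.config_hash(),
                "seed": cfg.seed,
                "mode": cfg.mode,
            },
        )
        report.to_tsv(out / "fold_enrichment.tsv", out / "window_tests.tsv")
        (out / "summary.json").write_text(report.to_json_summary() + "\n")
        (out / "summary.txt").write_text(report.summary() + "\n")
        sig = report.significant_windows()
        write_bed(sig, out / "significant_windows.bed", score_col="adj_p")
        for t in ("DEL", "DUP"):
            sub = report.window_table[report.window_table.sv_type == t]
            for cond in ("treat", "ctrl"):
                write_bedgraph(
                    sub, f"count_{cond}",
                    out / f"windows.{t}.{cond}.bedgraph",
                )
        for name in (
            "fold_enrichment.tsv", "window_tests.tsv", "summary.json",
            "significant_windows.bed",
        ):
            artifacts[name] = out / name
        return report
    run_stage("burden", burden_stage)

    if ref is not None:
        def repeats_stage():
            filtered = filter_rare_large(cs_treat, bcfg)
            obs = scan_callset(
                ref, filtered, cfg.flank_len, cfg.max_microhomology
            )
            null = permuted_breakpoint_null(
                ref, filtered, stage_seed(cfg.seed, "repeats"),
                cfg.flank_len, cfg.max_microhomology,
            )
            obs.to_tsv(out / "repeats.tsv")
            comparison = compare_to_null(obs, null)
            (out / "repeats_null.json").write_text(
                json.dumps(comparison, indent=2, sort_keys=True) + "\n"
            )
            artifacts["repeats.tsv"] = out / "repeats.tsv"
            artifacts["repeats_null.json"] = out / "repeats_null.json"
        run_stage("repeats", repeats_stage)

    cfg.to_yaml(out / "config.yaml")
    artifacts["config.yaml"] = out / "config.yaml"
    manifest = RunManifest(
        config=cfg.as_dict(),
        config_hash=cfg.config_hash(),
        version=__version__,
        stages=stages,
        checksums={name: _sha256(p) for name, p in sorted(artifacts.items())},
    )
    manifest.to_json(out / "manifest.json")
    return manifest
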