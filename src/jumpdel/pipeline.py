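"""End-to-end drivers: the experimental pipeline and the synthetic benchmark.

``run_pipeline`` reproduces the full processing chain for an experiment
pair (crosslinked sample + mono-adduct control): preprocess -> align ->
detect -> normalize -> subtract -> shift -> write. ``run_benchmark`` and
``benchmark_ladder`` drive the synthetic-read benchmark that calibrated the
aligner and detection parameters, scoring exact/close/incorrect matches
against encoded truth at each optimization stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from .alignment import AlignerConfig, align_reads, aligner_version
from .deletion_detect import (
    DetectConfig,
    detect_deletions_from_segments,
    load_segment_groups,
)
from .evaluate import AccuracyReport, score_dataset
from .io_formats import (
    ReferenceSequence,
    parse_reads,
    write_deletion_table,
    write_reads,
)
from .preprocess import MergeConfig, TrimConfig, preprocess_pairs
from .quantify import (
    ShiftConfig,
    compute_depth,
    count_deletions,
    normalize_counts,
    shift_sites,
    subtract_background,
)
from .simulate import MutationModel, SimConfig, generate_dataset, load_truth

log = logging.getLogger("jumpdel")


@dataclass
class PipelineConfig:
    """All stage configurations plus the random seed; JSON-serializable."""

    trim: TrimConfig = field(default_factory=TrimConfig)
    merge: MergeConfig = field(default_factory=MergeConfig)
    aligner: AlignerConfig = field(default_factory=AlignerConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    shift: ShiftConfig = field(default_factory=ShiftConfig)
    rng_seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        return cls(
            trim=TrimConfig(**raw["trim"]),
            merge=MergeConfig(**raw["merge"]),
            aligner=AlignerConfig(**raw["aligner"]),
            detect=DetectConfig(**raw["detect"]),
            shift=ShiftConfig(**raw["shift"]),
            rng_seed=raw.get("rng_seed", 0),
        )


def _stage(name: str):
    log.info("stage: %s", name)


def _prepare_sample(
    label: str,
    r1_path: str | Path,
    r2_path: str | Path | None,
    ref: ReferenceSequence,
    cfg: PipelineConfig,
    workdir: Path,
):
    """Preprocess and align one sample; returns parsed segment groups."""
    _stage(f"{label}: preprocess")
    if r2_path is not None:
        pairs = zip(parse_reads(r1_path, mate="1"), parse_reads(r2_path, mate="2"))
        merged, un1, un2, stats = preprocess_pairs(pairs, cfg.trim, cfg.merge)
        log.info("%s: %s", label, stats)
        merged_fq = workdir / f"{label}.merged.fastq"
        unmerged_fq = workdir / f"{label}.unmerged.fastq"
        write_reads(merged, merged_fq)
        n_un = write_reads(un1 + un2, unmerged_fq)
    else:
        from .preprocess import trim_read_quality

        kept = []
        for r in parse_reads(r1_path, mate="single"):
            t = trim_read_quality(r, cfg.trim)
            if t is not None:
                kept.append(t)
        merged_fq = workdir / f"{label}.single.fastq"
        write_reads(kept, merged_fq)
        unmerged_fq, n_un = None, 0
    _stage(f"{label}: align")
    sam_merged, sam_unmerged = align_reads(
        cfg.aligner, ref, merged_fq,
        unmerged_fq if n_un else None, out_dir=workdir,
    )
    sams = [str(sam_merged)] + ([str(sam_unmerged)] if sam_unmerged else [])
    return load_segment_groups(sams, ref)


def _profile_sample(label, groups, ref, cfg):
    _stage(f"{label}: detect")
    deletions, tally = detect_deletions_from_segments(groups, ref, cfg.detect)
    log.info("%s: %d deletions; diagnostics %s", label, len(deletions), dict(tally))
    _stage(f"{label}: quantify")
    depth = compute_depth(
        (segs for by_read in groups for segs in [by_read[r] for r in by_read]), ref
    )
    profile = normalize_counts(
        count_deletions(deletions), depth, sample_id=label, ref_name=ref.name
    )
    return profile, tally


def run_pipeline(
    xlink_r1: str | Path,
    ctrl_r1: str | Path,
    ref: ReferenceSequence,
    out_path: str | Path,
    xlink_r2: str | Path | None = None,
    ctrl_r2: str | Path | None = None,
    cfg: PipelineConfig | None = None,
    workdir: str | Path | None = None,
):
    """Process a crosslinked/control sample pair into a deletion table.

    Returns the final (subtracted, shifted) DeletionProfile; the table is
    written to ``out_path`` with full parameter provenance in its header.
    """
    cfg = cfg or PipelineConfig()
    for label, path in (("crosslinked", xlink_r1), ("control", ctrl_r1)):
        if not Path(path).exists():
            raise FileNotFoundError(f"input stage: {label} reads not found: {path}")
    if workdir is None:
        tmp = tempfile.TemporaryDirectory(prefix="jumpdel_")
        workdir = Path(tmp.name)
    else:
        tmp = None
        workdir = Path(workdir)
        workdir.mkdir(parents=True, exist_ok=True)
    try:
        xg = _prepare_sample("xlink", xlink_r1, xlink_r2, ref, cfg, workdir)
        cg = _prepare_sample("ctrl", ctrl_r1, ctrl_r2, ref, cfg, workdir)
        xprof, _ = _profile_sample("xlink", xg, ref, cfg)
        cprof, _ = _profile_sample("ctrl", cg, ref, cfg)
        _stage("subtract background")
        net = subtract_background(xprof, cprof)
        _stage("shift sites")
        final = shift_sites(net, cfg.shift)
        params = {
            "aligner_version": aligner_version(cfg.aligner),
            "shift_5p": cfg.shift.shift_5p,
            "shift_3p": cfg.shift.shift_3p,
            "min_deletion_length": cfg.detect.min_deletion_length,
            "max_insertion_length": cfg.detect.max_insertion_length,
            "edge_match_flank": cfg.detect.edge_match_flank,
            "remove_ambiguous": cfg.detect.remove_ambiguous,
        }
        write_deletion_table(final, out_path, params=params)
        return final
    finally:
        if tmp is not None:
            tmp.cleanup()


# ---------------------------------------------------------------------------
# synthetic benchmark


def _simulate_and_align(
    mode: str,
    n_reads: int,
    seed: int,
    workdir: Path,
    ref: ReferenceSequence,
    aligner_cfgs: dict[str, AlignerConfig],
    mutation_model: MutationModel | None = None,
):
    """Generate one synthetic dataset and align it under each config."""
    sim_cfg = SimConfig(mode=mode, n_reads=n_reads, rng_seed=seed)
    model = mutation_model if mutation_model is not None else MutationModel()
    fq = workdir / f"{mode}.fastq"
    truth_tsv = workdir / f"{mode}.truth.tsv"
    generate_dataset(ref, sim_cfg, model, fq, truth_tsv)
    truth = load_truth(truth_tsv)
    groups = {}
    for name, acfg in aligner_cfgs.items():
        sam, _ = align_reads(acfg, ref, fq, out_dir=workdir / name)
        groups[name] = load_segment_groups([str(sam)], ref)
    return truth, groups


def run_benchmark(
    mode: str = "deletion",
    n_reads: int = 100_000,
    seed: int = 1,
    aligner_cfg: AlignerConfig | None = None,
    detect_cfg: DetectConfig | None = None,
    ref: ReferenceSequence | None = None,
    workdir: str | Path | None = None,
    mutation_model: MutationModel | None = None,
) -> AccuracyReport:
    """Simulate, align and detect one configuration; score against truth."""
    from .simulate import default_benchmark_reference

    ref = ref or default_benchmark_reference()
    aligner_cfg = aligner_cfg or AlignerConfig()
    detect_cfg = detect_cfg or DetectConfig()
    with tempfile.TemporaryDirectory(prefix="jumpdel_bench_") as tmp:
        wd = Path(workdir) if workdir else Path(tmp)
        wd.mkdir(parents=True, exist_ok=True)
        truth, groups = _simulate_and_align(
            mode, n_reads, seed, wd, ref, {"run": aligner_cfg}, mutation_model
        )
        deletions, _ = detect_deletions_from_segments(groups["run"], ref, detect_cfg)
        return score_dataset(deletions, truth)


def benchmark_ladder(
    mode: str = "deletion",
    n_reads: int = 100_000,
    seed: int = 1,
    ref: ReferenceSequence | None = None,
    workdir: str | Path | None = None,
) -> dict[str, float]:
    """The four-stage optimization ladder on one synthetic dataset.

    Stages: (1) aligner defaults, no corrections; (2) optimized scoring
    parameters; (3) + ambiguous-deletion removal; (4) + exact edge
    matching. Exact-match percentages for stages 1-2 use all reads as the
    denominator; once ambiguous deletions are removed (stages 3-4) the
    denominator is restricted to reads whose encoded deletion is
    unambiguous, since ambiguous encodings are removed by construction.
    Also reports the fraction of reads with any detection at stage 1.
    """
    from .simulate import default_benchmark_reference

    ref = ref or default_benchmark_reference()
    cfgs = {
        "default": AlignerConfig.bwa_defaults(),
        "optimized": AlignerConfig(),
    }
    base = dict(remove_ambiguous=False, enforce_edges=False)
    with tempfile.TemporaryDirectory(prefix="jumpdel_ladder_") as tmp:
        wd = Path(workdir) if workdir else Path(tmp)
        wd.mkdir(parents=True, exist_ok=True)
        truth, groups = _simulate_and_align(mode, n_reads, seed, wd, ref, cfgs)

        def detect(which, **kw):
            dels, _ = detect_deletions_from_segments(
                groups[which], ref, DetectConfig(**{**base, **kw})
            )
            return dels

        truth_unamb = {rid: t for rid, t in truth.items() if not t.ambiguous}

        def score_restricted(dels):
            subset = [d for d in dels if d.read_id in truth_unamb]
            return score_dataset(subset, truth_unamb)

        d1 = detect("default")
        d2 = detect("optimized")
        d3 = detect("optimized", remove_ambiguous=True)
        d4 = detect("optimized", remove_ambiguous=True, enforce_edges=True)

        r1 = score_dataset(d1, truth)
        r2 = score_dataset(d2, truth)
        r3 = score_restricted(d3)
        r4 = score_restricted(d4)
        return {
            "default_params": r1.pct_exact,
            "optimized_params": r2.pct_exact,
            "plus_ambiguity_removal": r3.pct_exact,
            "plus_edge_matching": r4.pct_exact,
            "detected_fraction_default": r1.pct_detected,
            "n_reads": len(truth),
            "n_reads_unambiguous": len(truth_unamb),
        }
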