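"""End-to-end orchestration: simulate (or load) -> filter -> call peaks per
replicate -> replicate consensus -> ectopic filter -> coverage -> partition
against control -> report.

A run is described by a single config document (YAML/JSON-compatible dict)
with one designated control condition; every random consumer derives its
sub-seed from the master seed, so a rerun with the same config is
byte-identical. Reports carry both bases and kb (1 decimal) to avoid
rounding ambiguity, and the common/new partition of every condition
against the control satisfies exact base conservation.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from .calling import PeakCallParams, call_peaks, peaks_to_peakset, write_narrowpeak
from .genome import CentromereMask, GenomeSpec
from .intervals import (
    PeakSet,
    common_new_partition,
    default_min_support,
    ectopic_filter,
    peak_coverage,
    replicated_peaks,
)
from .io import DEFAULT_MIN_MAPQ, read_alignments, read_bed, write_bed
from .reads import ReadSet
from .simulate import (
    FeatureFolds,
    SimulationParams,
    TruthSet,
    make_genome,
    plant_features,
    simulate_reads,
)
from .subsample import compare_conditions, equalized_coverage

log = logging.getLogger(__name__)

__all__ = ["ConditionSpec", "RunConfig", "ConditionReport", "run_knockdown_comparison"]


@dataclass
class ConditionSpec:
    """One experimental condition: either simulation parameters or file paths."""

    name: str
    # simulation mode
    n_sharp: int = 0
    sharp_length: int = 1000
    domain_kb: float = 0.0
    folds: FeatureFolds = field(default_factory=FeatureFolds)
    depth: int = 200_000
    input_depth: int | None = None
    n_replicates: int = 3
    paired: bool = False
    extends: str | None = None  # inherit another condition's planted truth
    # file mode
    chip_paths: tuple[str, ...] = ()
    input_paths: tuple[str, ...] = ()

    @property
    def from_files(self) -> bool:
        return bool(self.chip_paths)


@dataclass
class RunConfig:
    """Config for a knockdown-comparison run. `control` names the condition
    every other condition is partitioned against."""

    conditions: list[ConditionSpec]
    control: str
    seed: int = 0
    genome: GenomeSpec | None = None
    genome_params: dict = field(default_factory=dict)
    peak_params: PeakCallParams = field(default_factory=PeakCallParams)
    min_support: int | None = None  # None -> 3 when n>=3 else n
    min_mapq: int = DEFAULT_MIN_MAPQ
    subsample: dict | None = None  # {ip_depth, input_depth, trials}

    def __post_init__(self) -> None:
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("condition names must be unique")
        if self.control not in names:
            raise ValueError(f"control condition {self.control!r} not defined")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        genome = None
        gp = dict(d.get("genome", {}))
        if "file" in gp:
            genome = GenomeSpec.from_yaml(gp.pop("file"))
        conditions = []
        for name, cd in d["conditions"].items():
            cd = dict(cd)
            folds = FeatureFolds(**cd.pop("folds", {}))
            cd.pop("name", None)
            conditions.append(
                ConditionSpec(
                    name=name,
                    folds=folds,
                    chip_paths=tuple(cd.pop("chip", ())),
                    input_paths=tuple(cd.pop("input", ())),
                    **cd,
                )
            )
        pp = PeakCallParams(**d.get("peak_params", {}))
        return cls(
            conditions=conditions,
            control=d["control"],
            seed=int(d.get("seed", 0)),
            genome=genome,
            genome_params=gp,
            peak_params=pp,
            min_support=d.get("min_support"),
            min_mapq=int(d.get("min_mapq", DEFAULT_MIN_MAPQ)),
            subsample=d.get("subsample"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ConditionReport:
    """Machine-readable condition summary (replicated ectopic coverage and
    its common/new partition against the control)."""

    condition: str
    n_replicates: int
    replicated_ectopic_bases: int
    truth_ectopic_bases: int | None = None
    common_bases: int | None = None
    new_bases: int | None = None
    control_only_bases: int | None = None
    subsample_mean_kb: float | None = None
    subsample_sd_kb: float | None = None
    t_vs_control: float | None = None
    p_vs_control: float | None = None

    @property
    def replicated_ectopic_kb(self) -> float:
        return self.replicated_ectopic_bases / 1000.0

    def to_dict(self) -> dict:
        d = {
            "condition": self.condition,
            "n_replicates": self.n_replicates,
            "replicated_ectopic_bases": self.replicated_ectopic_bases,
            "replicated_ectopic_kb": round(self.replicated_ectopic_kb, 1),
        }
        if self.truth_ectopic_bases is not None:
            d["truth_ectopic_bases"] = self.truth_ectopic_bases
        if self.common_bases is not None:
            d.update(
                common_bases=self.common_bases,
                common_kb=round(self.common_bases / 1000.0, 1),
                new_bases=self.new_bases,
                new_kb=round(self.new_bases / 1000.0, 1),
                control_only_bases=self.control_only_bases,
                control_only_kb=round(self.control_only_bases / 1000.0, 1),
            )
        if self.subsample_mean_kb is not None:
            d.update(
                subsample_mean_kb=round(self.subsample_mean_kb, 1),
                subsample_sd_kb=round(self.subsample_sd_kb, 1),
            )
        if self.p_vs_control is not None:
            d.update(
                t_vs_control=round(self.t_vs_control, 4),
                p_vs_control=float(f"{self.p_vs_control:.4g}"),
            )
        return d


def _condition_reads(
    cond: ConditionSpec, config: RunConfig, genome: GenomeSpec, idx: int,
    truths: dict[str, "TruthSet | None"],
) -> tuple[list[ReadSet], list[ReadSet], TruthSet | None]:
    """Load or simulate (chip replicates, input replicates, truth)."""
    if cond.from_files:
        chip = [read_alignments(p, config.min_mapq) for p in cond.chip_paths]
        inputs = [read_alignments(p, config.min_mapq) for p in cond.input_paths]
        if len(inputs) == 1 and len(chip) > 1:
            inputs = inputs * len(chip)
        return chip, inputs, None
    base = None
    if cond.extends is not None:
        if cond.extends not in truths or truths[cond.extends] is None:
            raise ValueError(
                f"condition {cond.name!r} extends {cond.extends!r}, which must "
                "be a simulated condition defined earlier in the config"
            )
        base = truths[cond.extends]
    truth = plant_features(
        genome,
        n_sharp=cond.n_sharp,
        domain_kb=cond.domain_kb,
        folds=cond.folds,
        seed=[config.seed, idx, 0],
        sharp_length=cond.sharp_length,
        base=base,
    )
    params = SimulationParams(
        depth=cond.depth,
        n_replicates=cond.n_replicates,
        paired=cond.paired,
        seed=(config.seed * 1000 + idx) % (2**31),
    )
    chip = simulate_reads(genome, truth, params, "chip")
    in_depth = cond.input_depth or cond.depth
    in_params = SimulationParams(
        depth=in_depth,
        n_replicates=cond.n_replicates,
        paired=cond.paired,
        seed=(config.seed * 1000 + idx + 500) % (2**31),
    )
    inputs = simulate_reads(genome, truth, in_params, "input")
    # apply the MAPQ filter exactly as for file input
    chip = [r.filter_mapq(config.min_mapq) for r in chip]
    inputs = [r.filter_mapq(config.min_mapq) for r in inputs]
    return chip, inputs, truth


def run_knockdown_comparison(config: RunConfig, outdir: str | None = None) -> dict:
    """Run the full comparison; returns {"conditions": [report...], ...}.

    Per condition: per-replicate peak calling against matched input ->
    replicate consensus (min_support) -> centromere-exclusion filter ->
    peak coverage; then the common/new partition against the control's
    final peak set. Writes summary.tsv / summary.json and per-condition
    BEDs when `outdir` is given.
    """
    genome = config.genome or make_genome(**config.genome_params)
    mask: CentromereMask = genome.centromeres
    if outdir:
        os.makedirs(outdir, exist_ok=True)

    final_sets: dict[str, PeakSet] = {}
    truths: dict[str, TruthSet | None] = {}
    reports: dict[str, ConditionReport] = {}
    pools: dict[str, tuple[list[ReadSet], list[ReadSet]]] = {}

    for idx, cond in enumerate(config.conditions):
        try:
            chip, inputs, truth = _condition_reads(cond, config, genome, idx, truths)
            rep_sets = []
            for r, (c, i) in enumerate(zip(chip, inputs)):
                peaks = call_peaks(c, i, genome, config.peak_params)
                ps = peaks_to_peakset(peaks, f"{cond.name}_rep{r + 1}")
                rep_sets.append(ps)
                if outdir:
                    write_narrowpeak(
                        peaks, os.path.join(outdir, f"{cond.name}_rep{r + 1}.narrowPeak")
                    )
            support = config.min_support or default_min_support(len(rep_sets))
            consensus = replicated_peaks(rep_sets, support)
            ectopic = ectopic_filter(consensus, mask).relabel(cond.name)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed for condition {cond.name!r}: {exc}"
            ) from exc
        final_sets[cond.name] = ectopic
        truths[cond.name] = truth
        pools[cond.name] = (chip, inputs)
        reports[cond.name] = ConditionReport(
            condition=cond.name,
            n_replicates=len(rep_sets),
            replicated_ectopic_bases=peak_coverage(ectopic),
            truth_ectopic_bases=(
                truth.ectopic_coverage_bases if truth is not None else None
            ),
        )
        if outdir:
            write_bed(ectopic, os.path.join(outdir, f"{cond.name}_replicated_ectopic.bed"))

    control_set = final_sets[config.control]
    for name, ps in final_sets.items():
        if name == config.control:
            continue
        part = common_new_partition(control_set, ps)
        rep = reports[name]
        rep.common_bases = part.common_bases
        rep.new_bases = part.new_bases
        rep.control_only_bases = part.control_only_bases

    sub_results = {}
    if config.subsample:
        ss = config.subsample
        for cond in config.conditions:
            chip, inputs = pools[cond.name]
            res = equalized_coverage(
                chip,
                inputs,
                genome,
                mask,
                ip_depth=int(ss["ip_depth"]),
                input_depth=int(ss["input_depth"]),
                trials=int(ss.get("trials", 3)),
                peak_params=config.peak_params,
                seed=config.seed,
                condition=cond.name,
            )
            sub_results[cond.name] = res
            reports[cond.name].subsample_mean_kb = res.mean_kb
            reports[cond.name].subsample_sd_kb = res.sd_kb
        ctrl = sub_results[config.control]
        for name, res in sub_results.items():
            if name == config.control:
                continue
            try:
                t, p = compare_conditions(res, ctrl)
                reports[name].t_vs_control = t
                reports[name].p_vs_control = p
            except ValueError as exc:
                log.warning("t-test for %s vs control skipped: %s", name, exc)

    summary = {
        "seed": config.seed,
        "control": config.control,
        "min_support": config.min_support
        or default_min_support(config.conditions[0].n_replicates),
        "conditions": [reports[c.name].to_dict() for c in config.conditions],
    }
    if outdir:
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        _write_summary_tsv(summary, os.path.join(outdir, "summary.tsv"))
        genome.to_yaml(os.path.join(outdir, "genome.yaml"))
    summary["final_sets"] = final_sets
    summary["truths"] = truths
    summary["subsample_results"] = sub_results
    return summary


def _write_summary_tsv(summary: dict, path) -> None:
    cols = [
        "condition",
        "n_replicates",
        "replicated_ectopic_kb",
        "common_kb",
        "new_kb",
        "control_only_kb",
        "subsample_mean_kb",
        "subsample_sd_kb",
        "p_vs_control",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rep in summary["conditions"]:
            fh.write(
                "\t".join(str(rep.get(c, "")) for c in cols) + "\n"
            )
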