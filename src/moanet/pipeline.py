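"""Configuration-driven orchestration of the full modeling workflow.

``run_pipeline`` executes the three stages end to end — data compilation
(scenario generation or file loading), mathematical model generation
(response network + constraint-trained solution ensembles), and model-output
analyses (relationship score table, consensus MoA graph, perturbed-set
overlap, differential activity) — and writes every artifact under one output
directory together with an echo of the exact configuration used, so a run is
reproducible from its own report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ann_relationship as ann
from . import moa_comparator as cmp_mod
from .knowledge_base import (
    DrugCharacterization,
    MotiveCharacterization,
    TruthTable,
    combine_drugs,
    read_drug_characterizations,
    read_motive_characterizations,
    read_truth_table,
)
from .network_builder import (
    Interactome,
    build_response_network,
    export_network,
    load_interactome,
    network_stats,
)
from .propagation_model import (
    MoAModel,
    TrainConfig,
    derive_seed,
    ensemble_accuracy,
    predicted_activity,
    sample_solutions,
    save_ensemble,
)
from .synthetic_data import SyntheticScenario, hemophilia_toy_scenario, signal_scenario

logger = logging.getLogger("moanet")


def _stimulus_seed(master_seed: int, stimulus: dict[str, int]) -> int:
    import zlib

    digest = zlib.crc32(repr(sorted(stimulus.items())).encode()) % 1_000_003
    return derive_seed(master_seed, 1000 + digest)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All knobs of one pipeline run; round-trips through YAML unchanged.

    Inputs are either a named synthetic scenario ("signal" or "toy") with a
    seed, or explicit file paths (interactome + drug/motive characterizations
    + truth table).  The remaining fields hold the operational constants of
    the method: the 10% very-common adverse-reaction frequency, the 5-report
    evidence floor, the 77/38 score bins, the 0.5 differential-activity
    threshold, the 100-solution ensemble size, and the epsilon/tau floors of
    the comparison analyses.
    """

    scenario: str = "toy"              # "signal" | "toy" | "files"
    master_seed: int = 0
    output_dir: str = "moanet_run"
    interactome_path: str | None = None
    drugs_path: str | None = None
    motives_path: str | None = None
    truth_table_path: str | None = None
    combination_a: list[str] = field(default_factory=list)
    combination_b: list[str] = field(default_factory=list)
    ensemble_size: int = 100
    accuracy_floor: float = 0.9
    ae_frequency_threshold: float = 0.10
    min_reports: int = 5
    high_score_min: float = 77.0
    medium_score_min: float = 38.0
    diff_threshold: float = 0.5
    weight_eps: float = 0.05
    activity_eps: float = 0.05
    perturbation_floor: float = 0.05
    max_nodes: int = 30
    k_folds: int = 5
    n_null: int = 99
    sa_steps: int = 200
    include_drug_targets_as_seeds: bool = True

    def validate(self) -> None:
        if self.scenario not in ("signal", "toy", "files"):
            raise ValueError(f"unknown scenario kind {self.scenario!r}")
        if self.scenario == "files":
            for label, p in (
                ("interactome_path", self.interactome_path),
                ("drugs_path", self.drugs_path),
                ("motives_path", self.motives_path),
                ("truth_table_path", self.truth_table_path),
            ):
                if p is None:
                    raise ValueError(f"scenario 'files' requires {label}")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{label}: {p} does not exist")
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if not (0 < self.ae_frequency_threshold <= 1):
            raise ValueError("ae_frequency_threshold outside (0, 1]")
        if self.min_reports < 1:
            raise ValueError("min_reports must be >= 1")
        if not (0 <= self.medium_score_min < self.high_score_min <= 100):
            raise ValueError("score bins must satisfy 0 <= medium < high <= 100")
        for name in ("diff_threshold", "weight_eps", "activity_eps",
                     "perturbation_floor", "accuracy_floor"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} outside [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class ComparisonReport:
    """Outputs of comparing two combination stimuli on a shared constraint set."""

    moa_a: MoAModel
    moa_b: MoAModel
    overlap: cmp_mod.OverlapReport
    differential: cmp_mod.DifferentialActivityReport
    graph: cmp_mod.MoAGraph
    threshold: float


@dataclass
class RunReport:
    config: RunConfig
    outputs: dict[str, str]
    metrics: dict[str, float]


def _load_inputs(
    config: RunConfig,
) -> tuple[Interactome, list[DrugCharacterization], list[MotiveCharacterization], TruthTable]:
    if config.scenario == "files":
        interactome = load_interactome(config.interactome_path)
        drugs = read_drug_characterizations(config.drugs_path)
        motives = read_motive_characterizations(config.motives_path)
        table = read_truth_table(config.truth_table_path, drugs, motives)
        return interactome, drugs, motives, table
    if config.scenario == "toy":
        sc = hemophilia_toy_scenario(seed=config.master_seed)
    else:
        sc = signal_scenario(seed=config.master_seed)
    assert sc.truth_table is not None
    return sc.interactome, sc.drugs, sc.conditions, sc.truth_table


def _default_combinations(
    config: RunConfig, drugs: list[DrugCharacterization]
) -> tuple[DrugCharacterization, DrugCharacterization]:
    names = {d.name for d in drugs}
    if config.combination_a and config.combination_b:
        by_name = {d.name: d for d in drugs}
        a = combine_drugs("+".join(config.combination_a),
                          *[by_name[n] for n in config.combination_a])
        b = combine_drugs("+".join(config.combination_b),
                          *[by_name[n] for n in config.combination_b])
        return a, b
    if {"emicizumab", "rFVIIa", "aPCC"} <= names:
        by_name = {d.name: d for d in drugs}
        return (
            combine_drugs("emicizumab+rFVIIa", by_name["emicizumab"], by_name["rFVIIa"]),
            combine_drugs("emicizumab+aPCC", by_name["emicizumab"], by_name["aPCC"]),
        )
    ordered = sorted(drugs, key=lambda d: d.name)
    return ordered[0], combine_drugs(
        f"{ordered[0].name}+{ordered[1].name}", ordered[0], ordered[1]
    )


def compare_combinations(
    config: RunConfig,
    stimulus_a: DrugCharacterization,
    stimulus_b: DrugCharacterization,
    network,
    truth_table: TruthTable,
) -> ComparisonReport:
    """Model two combination stimuli against the same constraints and compare.

    Both ensembles are trained on the identical truth table; the comparison
    then runs perturbed-set overlap (excluding the union of both stimuli, so
    only indirectly driven proteins are compared), differential predicted
    activity, and a dual-map consensus MoA graph with per-combination
    presence flags.
    """
    tc = TrainConfig(sa_steps=config.sa_steps, accuracy_floor=config.accuracy_floor)
    # the ensemble seed is a function of the stimulus content, so identical
    # stimuli always yield identical MoA models under one master seed
    moa_a = sample_solutions(
        network, truth_table, stimulus_a.stimulus(), n=config.ensemble_size,
        seed=_stimulus_seed(config.master_seed, stimulus_a.stimulus()),
        config=tc, name=stimulus_a.name,
    )
    moa_b = sample_solutions(
        network, truth_table, stimulus_b.stimulus(), n=config.ensemble_size,
        seed=_stimulus_seed(config.master_seed, stimulus_b.stimulus()),
        config=tc, name=stimulus_b.name,
    )
    clamped_union = set(moa_a.stimulus) | set(moa_b.stimulus)
    set_a = cmp_mod.perturbed_protein_set(
        moa_a, config.perturbation_floor, exclude=clamped_union
    )
    set_b = cmp_mod.perturbed_protein_set(
        moa_b, config.perturbation_floor, exclude=clamped_union
    )
    overlap = cmp_mod.overlap_analysis(set_a, set_b)

    acts_a, acts_b = predicted_activity(moa_a), predicted_activity(moa_b)
    differential = cmp_mod.differential_activity(acts_b, acts_a, config.diff_threshold)

    freq_a = cmp_mod.interaction_frequencies(moa_a, config.weight_eps, config.activity_eps)
    freq_b = cmp_mod.interaction_frequencies(moa_b, config.weight_eps, config.activity_eps)
    merged = {k: max(freq_a.get(k, 0.0), freq_b.get(k, 0.0)) for k in freq_a}
    threshold = cmp_mod.optimize_frequency_threshold(merged, config.max_nodes)
    graph = cmp_mod.consensus_moa_graph(
        [freq_a, freq_b], threshold, [acts_a, acts_b],
        map_names=(stimulus_a.name, stimulus_b.name),
    )
    return ComparisonReport(moa_a, moa_b, overlap, differential, graph, threshold)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute curation -> network -> training -> scoring -> comparison."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "FAILED").unlink(missing_ok=True)
    config.to_yaml(out / "config.yaml")
    outputs: dict[str, str] = {"config": str(out / "config.yaml")}
    metrics: dict[str, float] = {}

    def stage(name: str):
        logger.info("stage %s", name)
        return _StageTimer(name, out, metrics)

    try:
        with stage("inputs"):
            interactome, drugs, motives, truth_table = _load_inputs(config)
    except Exception as exc:
        raise PipelineError("inputs", exc) from exc

    try:
        with stage("network"):
            seeds = {e.protein.accession for m in motives for e in m.effectors}
            if config.include_drug_targets_as_seeds:
                seeds |= {t.protein.accession for d in drugs for t in d.targets}
            response = build_response_network(interactome, seeds)
            stats = network_stats(response)
            metrics["n_proteins"] = float(stats.n_proteins)
            metrics["n_interactions"] = float(stats.n_interactions)
            net_path = out / "response_network.graphml"
            export_network(response, net_path)
            outputs["response_network"] = str(net_path)
    except Exception as exc:
        raise PipelineError("network", exc) from exc

    try:
        with stage("training"):
            stim_a, stim_b = _default_combinations(config, drugs)
            comparison = compare_combinations(
                config, stim_a, stim_b, response, truth_table
            )
            for tag, moa in (("a", comparison.moa_a), ("b", comparison.moa_b)):
                d = out / f"ensemble_{tag}"
                save_ensemble(moa, d)
                outputs[f"ensemble_{tag}"] = str(d)
                metrics[f"ensemble_{tag}_mean_accuracy"] = ensemble_accuracy(moa)
                metrics[f"ensemble_{tag}_n_solutions"] = float(moa.n_solutions)
    except Exception as exc:
        raise PipelineError("training", exc) from exc

    try:
        with stage("scoring"):
            # stratified CV needs at least one member of each class per fold
            min_class = min(len(truth_table.positives), len(truth_table.negatives))
            k_folds = max(2, min(config.k_folds, min_class))
            if k_folds != config.k_folds:
                logger.info("reducing k_folds from %d to %d for class sizes",
                            config.k_folds, k_folds)
            clf, cv_acc = ann.train_classifier(
                truth_table, response, k_folds=k_folds,
                seed=derive_seed(config.master_seed, 201),
            )
            metrics["classifier_cv_accuracy"] = cv_acc
            rows = []
            processes = list(motives)
            outcome_effs = {e for m in motives for e in m.effectors}
            processes.append(MotiveCharacterization("outcome", frozenset(outcome_effs)))
            # scoring uses the same untrained-propagation featurization the
            # classifier was trained on; the trained ensembles feed the
            # comparison analyses below
            for stim in (stim_a, stim_b):
                for proc in processes:
                    feats = ann.featurize_pair(
                        stim.stimulus(), proc.effectors, response
                    )
                    score = ann.score_pair(clf, feats)
                    null = ann.null_scores(
                        clf, response, len(stim.targets), len(proc.effectors),
                        n_null=config.n_null,
                        seed=derive_seed(config.master_seed, 202),
                    )
                    rows.append(
                        {
                            "combination": stim.name,
                            "process": proc.name,
                            "score_pct": round(score, 2),
                            "p_value": round(ann.calibrate_pvalue(score, null), 4),
                            "category": ann.categorize_score(score),
                        }
                    )
            score_path = out / "score_table.tsv"
            pd.DataFrame(rows).to_csv(score_path, sep="\t", index=False)
            outputs["score_table"] = str(score_path)
    except Exception as exc:
        raise PipelineError("scoring", exc) from exc

    try:
        with stage("comparison"):
            dot_path = out / "moa.dot"
            cmp_mod.export_moa_dot(comparison.graph, dot_path)
            outputs["moa_dot"] = str(dot_path)
            overlap_path = out / "overlap.tsv"
            cmp_mod.write_overlap_report(comparison.overlap, overlap_path)
            outputs["overlap"] = str(overlap_path)
            diff_path = out / "differential_activity.tsv"
            comparison.differential.to_frame().to_csv(diff_path, sep="\t", index=False)
            outputs["differential"] = str(diff_path)
            metrics["n_perturbed_a"] = float(comparison.overlap.n_a)
            metrics["n_perturbed_b"] = float(comparison.overlap.n_b)
            metrics["a_subset_of_b"] = float(comparison.overlap.a_subset_of_b)
            metrics["n_significant_differential"] = float(
                len(comparison.differential.significant)
            )
            metrics["frequency_threshold"] = comparison.threshold
    except Exception as exc:
        raise PipelineError("comparison", exc) from exc

    report = RunReport(config, outputs, metrics)
    (out / "report.json").write_text(
        json.dumps({"config": asdict(config), "outputs": outputs, "metrics": metrics},
                   indent=1)
    )
    return report


class _StageTimer:
    def __init__(self, name: str, out: Path, metrics: dict[str, float]):
        self.name = name
        self.out = out
        self.metrics = metrics

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        self.metrics[f"wall_time_{self.name}_s"] = round(dt, 3)
        if exc_type is not None:
            (self.out / "FAILED").write_text(f"stage {self.name}: {exc}\n")
        logger.info("stage %s finished in %.2fs", self.name, dt)
        return False
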