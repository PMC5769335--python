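"""The `dice` driver: chain generation, completion, consensus, evaluation,
selection and significance into one reproducible run.

Stage order: prepare -> generate_array -> complete_by_knn -> per-k consensus
matrices -> internal indices per base algorithm -> rank -> trim/weights ->
PAC per k -> select_k -> consensus methods at the selected k -> ensemble
evaluation -> optional external indices and significance testing. All stage
outputs can be persisted so any stage can be rerun independently.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import consensus as cons
from .consensus import CONSENSUS_METHODS, EnsembleSolution, run_method
from .data_prep import DataMatrix, prepare
from .evaluation import (
    ConsensusMatrix,
    EvaluationConfig,
    ValidityTable,
    consensus_cdf,
    consensus_matrix,
    delta_auc,
    external_indices,
    internal_indices,
    pac,
    select_k,
)
from .generation import ClusteringArray, GenerationConfig, complete_by_knn, derive_seed, generate_array
from .selection import TrimConfig, compute_weights, rank_algorithms, trim, weighted_consensus_matrix
from .significance import sigclust

__all__ = ["DiceConfig", "DiceResult", "dice"]

logger = logging.getLogger("dce.pipeline")

FLOAT_FMT = "%.10g"


@dataclass
class DiceConfig:
    generation: GenerationConfig = field(default_factory=GenerationConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    trim: TrimConfig = field(default_factory=TrimConfig)
    consensus_methods: tuple[str, ...] = CONSENSUS_METHODS
    lce_dc: float = 0.8
    scale: bool = False
    pinned_k: int | None = None
    run_sigclust: bool = False
    sigclust_n_sim: int = 100
    reference_labels: np.ndarray | None = None
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.consensus_methods:
            raise ValueError("consensus_methods must be non-empty")
        bad = [m for m in self.consensus_methods if m not in CONSENSUS_METHODS]
        if bad:
            raise ValueError(f"unknown consensus method(s) {bad}; supported: {CONSENSUS_METHODS}")
        if not 0 <= self.lce_dc <= 1:
            raise ValueError("lce_dc must lie in [0, 1]")
        # the generation seed follows the run seed unless set explicitly
        if self.generation.seed == 0 and self.seed != 0:
            self.generation.seed = self.seed


@dataclass
class DiceResult:
    selected_k: int
    solutions: dict[str, EnsembleSolution]
    consensus_matrices: dict[int, ConsensusMatrix]
    pac_per_k: dict[int, float]
    delta_auc_per_k: dict[int, float]
    validity: ValidityTable
    ranking: list[str]
    kept_algorithms: list[str]
    weights: pd.Series | None
    external: dict[str, dict[str, float]] | None
    significance: list[dict] | None
    array: ClusteringArray
    config: DiceConfig


def _stage(name):
    logger.info("stage: %s", name)


def dice(dm: DataMatrix, cfg: DiceConfig | None = None) -> DiceResult:
    """Run the full ensemble pipeline on a prepared (or raw numeric) matrix."""
    cfg = cfg or DiceConfig()
    gen = cfg.generation

    _stage("prepare")
    dm = prepare(dm, scale=cfg.scale, impute_missing=False)

    _stage("generate")
    arr = generate_array(dm, gen)

    _stage("complete")
    arr = complete_by_knn(arr, dm, knn_k=gen.knn_k)

    _stage("evaluate_base")
    # per (algorithm, k): majority consensus of that algorithm's reps -> indices
    records = []
    base_labels: dict[tuple[str, int], np.ndarray] = {}
    for alg in arr.algorithms:
        for k in arr.k_values:
            try:
                lm, _ = arr.k_slice(k, algorithms=[alg])
            except ValueError:
                continue
            sol = cons.majority_vote(lm, k)
            base_labels[(alg, k)] = sol.labels
            records.append((alg, k, internal_indices(dm, sol.labels, cfg.evaluation.index_set)))
    validity = ValidityTable.from_records(records)

    _stage("rank")
    ranking = rank_algorithms(validity, cfg.trim)

    _stage("trim")
    kept = ranking[: cfg.trim.top_n] if cfg.trim.top_n else list(ranking)
    trimmed = trim(arr, ranking, len(kept)) if cfg.trim.top_n else arr
    weights = None
    if cfg.trim.reweigh:
        wt_table = ValidityTable(validity.df.loc[validity.df.index.get_level_values("algorithm").isin(kept)], validity.directions)
        weights = compute_weights(wt_table)

    _stage("consensus_matrices")
    cms: dict[int, ConsensusMatrix] = {}
    for k in trimmed.k_values:
        lm, run_algs = trimmed.k_slice(k)
        if weights is not None:
            cms[k] = weighted_consensus_matrix(lm, run_algs, weights)
        else:
            cms[k] = consensus_matrix(lm, sample_ids=list(trimmed.sample_ids))

    _stage("select_k")
    ks = sorted(cms)
    pac_per_k = {k: pac(cms[k], cfg.evaluation.pac_lower, cfg.evaluation.pac_upper) for k in ks}
    dauc = delta_auc([consensus_cdf(cms[k]) for k in ks], ks)
    selected_k = cfg.pinned_k if cfg.pinned_k is not None else select_k(pac_per_k)

    _stage("consensus_methods")
    lm, _ = trimmed.k_slice(selected_k)
    solutions: dict[str, EnsembleSolution] = {}
    for method in cfg.consensus_methods:
        solutions[method] = run_method(
            method, lm, selected_k, cm=cms[selected_k], seed=derive_seed(cfg.seed, "consensus", method), dc=cfg.lce_dc
        )

    _stage("evaluate_ensembles")
    ens_records = [
        (f"ensemble:{m}", selected_k, internal_indices(dm, sol.labels, cfg.evaluation.index_set))
        for m, sol in solutions.items()
        if not sol.degenerate
    ]
    validity = ValidityTable.from_records(records + ens_records)

    external = None
    if cfg.reference_labels is not None:
        _stage("external_indices")
        ref = np.asarray(cfg.reference_labels, dtype=int)
        external = {m: external_indices(sol.labels, ref) for m, sol in solutions.items()}

    significance = None
    if cfg.run_sigclust:
        _stage("sigclust")
        significance = _sigclust_hierarchy(dm, solutions, selected_k, cfg)

    result = DiceResult(
        selected_k=selected_k,
        solutions=solutions,
        consensus_matrices=cms,
        pac_per_k=pac_per_k,
        delta_auc_per_k=dauc,
        validity=validity,
        ranking=ranking,
        kept_algorithms=kept,
        weights=weights,
        external=external,
        significance=significance,
        array=arr,
        config=cfg,
    )
    if cfg.output_dir is not None:
        _stage("write_outputs")
        write_outputs(result, dm, cfg.output_dir)
    return result


def _sigclust_hierarchy(dm: DataMatrix, solutions, selected_k: int, cfg: DiceConfig) -> list[dict]:
    """Top-down significance tests: the root 2-way split, then each final
    cluster's own best split. Raw (uncorrected) p-values."""
    out = []
    res = sigclust(dm, n_sim=cfg.sigclust_n_sim, seed=derive_seed(cfg.seed, "sigclust", "root"))
    out.append({"comparison": "root", "observed_ci": res.observed_ci, "p_value": res.p_value, "n_sim": res.n_sim})
    first = next(iter(solutions.values()))
    if selected_k > 2:
        for c in np.unique(first.labels):
            idx = np.nonzero(first.labels == c)[0]
            if idx.size < 10:
                continue
            sub = DataMatrix(dm.values[idx], [dm.sample_ids[i] for i in idx], list(dm.feature_ids))
            res = sigclust(sub, n_sim=cfg.sigclust_n_sim, seed=derive_seed(cfg.seed, "sigclust", int(c)))
            out.append(
                {"comparison": f"within_cluster_{c}", "observed_ci": res.observed_ci, "p_value": res.p_value, "n_sim": res.n_sim}
            )
    return out


def write_outputs(result: DiceResult, dm: DataMatrix, output_dir) -> None:
    """Persist labels, consensus matrices, validity table and run summary."""
    from pathlib import Path

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for method, sol in result.solutions.items():
        for sid, lab in zip(dm.sample_ids, sol.labels):
            rows.append({"sample_id": sid, "method": method, "k": sol.k, "label": int(lab)})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)

    for k, cm in result.consensus_matrices.items():
        pd.DataFrame(cm.values, index=dm.sample_ids, columns=dm.sample_ids).to_csv(
            out / f"consensus_k{k}.csv", float_format=FLOAT_FMT
        )

    result.validity.to_csv(out / "validity.csv")
    result.array.to_long_frame().to_csv(out / "clustering_array.csv", index=False)

    summary = {
        "selected_k": int(result.selected_k),
        "pac_per_k": {str(k): round(v, 10) for k, v in result.pac_per_k.items()},
        "delta_auc_per_k": {str(k): round(v, 10) for k, v in result.delta_auc_per_k.items()},
        "ranking": result.ranking,
        "kept_algorithms": result.kept_algorithms,
        "weights": None if result.weights is None else {a: round(float(w), 10) for a, w in result.weights.items()},
        "degenerate": {m: bool(s.degenerate) for m, s in result.solutions.items()},
        "external": result.external,
        "significance": result.significance,
        "seed": int(result.config.seed),
    }
    with open(out / "summary.json", "w") as f:
        json.dump(summary, f, indent=2)


def setup_logging(output_dir=None) -> None:
    """Timestamped, stage-tagged logging to stderr (and run.log if given)."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if output_dir is not None:
        from pathlib import Path

        Path(output_dir).mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(Path(output_dir) / "run.log"))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
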