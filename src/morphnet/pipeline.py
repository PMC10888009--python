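"""End-to-end orchestration: cohort -> similarity matrices -> sparsity-swept
metrics -> group statistics and score correlations -> classification grid.

Intermediates (per-subject matrices and AUC tables) are cached as text files
inside the output directory keyed by a hash of the stage-relevant config, so
reruns skip completed stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import BD_MDD_SUBMATRIX_REGIONS, run_grid, vectorize
from .graph_metrics import (
    DEFAULT_N_REFS,
    DEFAULT_THRESHOLDS,
    global_metrics,
    metric_curves,
    sparsity_threshold,
)
from .group_stats import compare_groups, fdr_bh, partial_correlation
from .io_formats import ROISampleSet, SubjectRecord, read_cohort, read_matrix, write_cohort, write_matrix
from .kls_network import SimilarityMatrix, build_similarity_matrix
from .synthetic_cohort import CohortDesign, generate_cohort

log = logging.getLogger("morphnet")


@dataclass
class RunConfig:
    output_dir: str = "morphnet_run"
    # input: either a synthetic design or paths to cohort files
    synthetic: dict = field(default_factory=dict)
    subject_table: str | None = None
    samples_file: str | None = None
    # sweep
    sweep_start: float = 0.10
    sweep_stop: float = 0.34
    sweep_step: float = 0.01
    n_random_refs: int = DEFAULT_N_REFS
    smallworld_seed: int = 0
    # stats
    permutations: int = 10_000
    q_level: float = 0.05
    stats_seed: int = 0
    # classification
    classification_folds: int = 5
    classification_perms: int = 0
    classification_seed: int = 0
    reducer_max_iter: int = 400
    n_trees: int = 500
    run_classification: bool = True
    run_stats: bool = True

    @property
    def thresholds(self) -> np.ndarray:
        n = int(round((self.sweep_stop - self.sweep_start) / self.sweep_step)) + 1
        return np.round(self.sweep_start + self.sweep_step * np.arange(n), 10)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _design_from_config(config: RunConfig) -> CohortDesign:
    from .synthetic_cohort import GroupEffect

    raw = dict(config.synthetic)
    effects = [GroupEffect(**e) for e in raw.pop("effects", [])]
    return CohortDesign(effects=effects, **raw)


def load_or_simulate(config: RunConfig) -> tuple[list[SubjectRecord], list[ROISampleSet]]:
    if config.subject_table and config.samples_file:
        return read_cohort(config.subject_table, config.samples_file)
    return generate_cohort(_design_from_config(config))


def build_networks(
    sample_sets: list[ROISampleSet], outdir: Path
) -> dict[str, SimilarityMatrix]:
    """Build (or load cached) per-subject KLS matrices."""
    matrix_dir = outdir / "matrices"
    matrix_dir.mkdir(parents=True, exist_ok=True)
    matrices: dict[str, SimilarityMatrix] = {}
    for ss in sample_sets:
        path = matrix_dir / f"{ss.subject_id}.csv"
        if path.exists():
            log.info("skip network construction for %s (cached)", ss.subject_id)
            labels, values = read_matrix(path)
            matrices[ss.subject_id] = SimilarityMatrix(labels=labels, values=values)
            continue
        t0 = time.perf_counter()
        m = build_similarity_matrix(ss)
        write_matrix(m.labels, m.values, path)
        # reload so cached and fresh runs share the serialized precision
        labels, values = read_matrix(path)
        matrices[ss.subject_id] = SimilarityMatrix(labels=labels, values=values)
        log.info("built network for %s in %.2fs", ss.subject_id, time.perf_counter() - t0)
    return matrices


def compute_aucs(
    matrices: dict[str, SimilarityMatrix],
    config: RunConfig,
    outdir: Path,
) -> dict[str, dict]:
    """Per-subject global and nodal AUC tables (cached as JSON)."""
    auc_dir = outdir / "aucs"
    auc_dir.mkdir(parents=True, exist_ok=True)
    tag = config.digest()
    aucs: dict[str, dict] = {}
    for sid, matrix in matrices.items():
        path = auc_dir / f"{sid}.json"
        if path.exists():
            with open(path) as fh:
                cached = json.load(fh)
            if cached.get("config_digest") == tag:
                log.info("skip metric sweep for %s (cached)", sid)
                aucs[sid] = cached
                continue
        t0 = time.perf_counter()
        sweep = metric_curves(
            matrix,
            thresholds=config.thresholds,
            n_random_refs=config.n_random_refs,
            seed=config.smallworld_seed,
        )
        entry = {
            "config_digest": tag,
            "global": sweep.global_auc(),
            "nodal": {k: v.tolist() for k, v in sweep.nodal_auc().items()},
            "sigma_curve": sweep.global_curves["sigma"].values.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(entry, fh, sort_keys=True)
        aucs[sid] = entry
        log.info("metric sweep for %s in %.2fs", sid, time.perf_counter() - t0)
    return aucs


def validate_sweep(
    matrices: dict[str, SimilarityMatrix],
    thresholds: np.ndarray | None = None,
    n_random_refs: int = DEFAULT_N_REFS,
    seed: int = 0,
) -> list[dict]:
    """Flag (subject, threshold) pairs where sigma <= 1 or the graph
    fragments; nothing is dropped, only reported."""
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("empty threshold list")
    from scipy.sparse.csgraph import connected_components

    flags = []
    for sid, matrix in matrices.items():
        for t_idx, s in enumerate(thresholds):
            g = sparsity_threshold(matrix, float(s))
            n_comp, _ = connected_components(g.adjacency, directed=False)
            if n_comp > 1:
                flags.append(
                    {"subject": sid, "sparsity": float(s), "reason": f"fragmented ({n_comp} components)"}
                )
            gm = global_metrics(g, n_random_refs=n_random_refs, seed=seed + 7919 * t_idx)
            if not (gm.sigma > 1.0):
                flags.append(
                    {"subject": sid, "sparsity": float(s), "reason": f"sigma {gm.sigma:.3f} <= 1.0"}
                )
    return flags


def _group_auc_tables(records, aucs):
    order = [r.subject_id for r in records]
    by_group: dict[str, list[str]] = {}
    for r in records:
        by_group.setdefault(r.group, []).append(r.subject_id)
    # sorted so fresh and cache-loaded runs iterate identically
    global_metric_names = sorted(aucs[order[0]]["global"])
    nodal_metric_names = sorted(aucs[order[0]]["nodal"])
    global_auc = {
        m: {g: np.array([aucs[s]["global"][m] for s in sids]) for g, sids in by_group.items()}
        for m in global_metric_names
    }
    nodal_auc = {
        m: {g: np.array([aucs[s]["nodal"][m] for s in sids]) for g, sids in by_group.items()}
        for m in nodal_metric_names
    }
    return global_auc, nodal_auc


def score_correlations(records, aucs, q_level: float = 0.05) -> list[dict]:
    """Partial correlations (age and sex as covariates) between network AUCs
    and clinical scores within each patient group, BH-corrected per family."""
    results = []
    for group in ("MDD", "BD"):
        members = [r for r in records if r.group == group]
        if len(members) < 6:
            continue
        age = np.array([r.age for r in members])
        sex = np.array([1.0 if r.sex == "F" else 0.0 for r in members])
        cov = np.column_stack([age, sex])
        cov_names = ["age", "sex"]
        keep = cov.std(axis=0) > 0  # tiny cohorts can have single-sex groups
        cov = cov[:, keep]
        cov_names = [n for n, k in zip(cov_names, keep) if k]
        scores = {"hamd": [r.hamd for r in members], "hama": [r.hama for r in members]}
        if group == "BD":
            scores["ymrs"] = [r.ymrs for r in members]
        for score_name, vals in scores.items():
            if any(v is None for v in vals):
                continue
            vals = np.asarray(vals, dtype=float)
            family = []
            for metric in sorted(aucs[members[0].subject_id]["global"]):
                x = np.array([aucs[r.subject_id]["global"][metric] for r in members])
                res = partial_correlation(
                    x, vals, cov, x_name=metric, y_name=score_name, covariate_names=cov_names
                )
                family.append(res)
            qs, _ = fdr_bh(np.array([r.p for r in family]), q_level)
            for res, qv in zip(family, qs):
                res.q = float(qv)
                results.append(
                    {
                        "group": group,
                        "metric": res.x_name,
                        "score": score_name,
                        "r": res.r,
                        "p": res.p,
                        "q": res.q,
                        "n": res.n,
                    }
                )
    return results


def run_pipeline(config: RunConfig) -> dict:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()

    records, sample_sets = load_or_simulate(config)
    write_cohort(records, sample_sets, outdir / "subjects.csv", outdir / "samples.csv")

    matrices = build_networks(sample_sets, outdir)
    aucs = compute_aucs(matrices, config, outdir)

    bundle: dict = {
        "provenance": {
            "version": __version__,
            "config_digest": config.digest(),
            "n_subjects": len(records),
            "groups": sorted({r.group for r in records}),
        }
    }

    if config.run_stats and len({r.group for r in records}) >= 2:
        global_auc, nodal_auc = _group_auc_tables(records, aucs)
        node_labels = sample_sets[0].region_labels
        comparisons = compare_groups(
            global_auc,
            nodal_auc,
            B=config.permutations,
            seed=config.stats_seed,
            q_level=config.q_level,
            node_labels=node_labels,
        )
        bundle["group_comparisons"] = {
            f"{g1}_vs_{g2}": [
                {
                    "metric": r.metric,
                    "node": r.node,
                    "observed_diff": r.observed_diff,
                    "p_perm": r.p_perm,
                    "q_fdr": r.q_fdr,
                    "direction": r.direction,
                }
                for r in rows
            ]
            for (g1, g2), rows in comparisons.items()
        }
        bundle["score_correlations"] = score_correlations(records, aucs, config.q_level)
        rows = [
            {"contrast": contrast, **row}
            for contrast, contrast_rows in bundle["group_comparisons"].items()
            for row in contrast_rows
        ]
        pd.DataFrame(rows).to_csv(outdir / "group_comparisons.csv", index=False)

    if config.run_classification:
        bundle["classification"] = classification_tables(records, matrices, config)
        pd.DataFrame(bundle["classification"]).to_csv(
            outdir / "classification_grid.csv", index=False
        )

    log.info("pipeline finished in %.2fs", time.perf_counter() - t_start)
    with open(outdir / "results.json", "w") as fh:
        json.dump(bundle, fh, sort_keys=True, indent=1)
    return bundle


def classification_tables(records, matrices, config: RunConfig) -> list[dict]:
    """The three standard tasks x full reducer/classifier grid."""
    groups = {r.group for r in records}
    tasks = []
    if "HC" in groups and groups & {"MDD", "BD"}:
        tasks.append(("hc-vs-patients", None))
    if {"BD", "MDD"} <= groups:
        tasks.append(("bd-vs-mdd", None))
        tasks.append(("bd-vs-mdd", BD_MDD_SUBMATRIX_REGIONS))
    rows = []
    for task, subset in tasks:
        positive = "patients" if task == "hc-vs-patients" else "BD"
        table, confound = make_task_table(records, matrices, task, region_subset=subset)
        reports = run_grid(
            table,
            confound=confound,
            k_folds=config.classification_folds,
            seed=config.classification_seed,
            n_perm=config.classification_perms,
            task=f"{task}:{table.provenance}",
            reducer_max_iter=config.reducer_max_iter,
            n_trees=config.n_trees,
        )
        for rep in reports:
            rep.positive_class = positive
            rows.append(
                {
                    "task": rep.task,
                    "positive_class": rep.positive_class,
                    "reducer": rep.reducer,
                    "classifier": rep.classifier,
                    "balanced_accuracy": rep.balanced_accuracy,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                    "fold_mean_balanced_accuracy": rep.fold_mean_balanced_accuracy,
                    "p_perm": rep.p_perm,
                }
            )
    return rows


def make_task_table(records, matrices, task: str, region_subset=None):
    """Build the FeatureTable and confound vector for one task.

    Positive class: patients for hc-vs-patients, BD for bd-vs-mdd.
    """
    if task == "hc-vs-patients":
        members = [r for r in records if r.group in ("HC", "MDD", "BD")]
        labels = np.array([0 if r.group == "HC" else 1 for r in members])
    elif task == "bd-vs-mdd":
        members = [r for r in records if r.group in ("BD", "MDD")]
        labels = np.array([1 if r.group == "BD" else 0 for r in members])
    else:
        raise ValueError(f"unknown task {task!r}")
    ids = [r.subject_id for r in members]
    table = vectorize([matrices[i] for i in ids], ids, labels, region_subset=region_subset)
    confound = np.array([r.medication_code for r in members], dtype=float)
    return table, confound
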