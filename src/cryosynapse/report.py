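"""Dataset-level summaries: per-mouse prevalence, correlations, aggregation.

Prevalence statistics treat the mouse, not the tomogram, as the biological
replicate: each mouse contributes one percentage (tomograms showing the
feature / tomograms scored in that compartment), and the dataset is
summarised as mean ± SEM across mice (sample sd, n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

COMPARTMENTS = ("PreSM", "PoSM", "vicinal")


class SchemaError(ValueError):
    pass


class ConsistencyError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


@dataclass
class PrevalenceResult:
    feature: str
    compartment: str
    per_mouse: pd.Series     # mouse_id -> percentage
    mean: float              # %
    sem: float               # %
    n_mice: int


def prevalence(
    table: pd.DataFrame, feature: str, compartment: str
) -> PrevalenceResult:
    """Per-mouse prevalence (%) of a boolean feature, mean ± SEM across mice.

    ``table`` rows are tomogram annotations with columns ``tomogram_id``,
    ``mouse_id``, ``compartment`` and one boolean/count column per feature.
    """
    for col in ("tomogram_id", "mouse_id", "compartment"):
        if col not in table.columns:
            raise SchemaError(f"annotation table lacks column {col!r}")
    if feature not in table.columns:
        raise SchemaError(f"unknown feature {feature!r}")
    if compartment not in set(table["compartment"]):
        raise SchemaError(f"no rows for compartment {compartment!r}")
    sub = table[table["compartment"] == compartment]
    present = sub[feature].astype(float) > 0
    per_mouse = 100.0 * present.groupby(sub["mouse_id"]).mean()
    n = len(per_mouse)
    sem = float(per_mouse.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return PrevalenceResult(
        feature=feature,
        compartment=compartment,
        per_mouse=per_mouse,
        mean=float(per_mouse.mean()),
        sem=sem,
        n_mice=n,
    )


def correlate(x, y) -> tuple[float, float, int]:
    """Pearson r with two-sided p from the t distribution (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(x)


def aggregate(results: list[dict]) -> dict:
    """Bundle per-synapse results into one dataset summary.

    Each entry carries a unique ``synapse_id`` and any of: ``crowding``
    (CrowdingResult), ``cleft`` (CleftSummary), ``clusters``
    (ClusterReport). Emits crowding class counts, cleft mean-of-means and
    pooled-mean stats, the cluster-count distribution, and the fractions
    of synapses with any cluster and with non-cleft (boundary or
    perisynaptic) clusters.
    """
    ids = [r["synapse_id"] for r in results]
    if len(set(ids)) != len(ids):
        raise ConsistencyError("duplicate synapse ids")
    out: dict = {"n_synapses": len(results)}

    crowd = [r["crowding"] for r in results if r.get("crowding") is not None]
    if crowd:
        out["crowding_class_counts"] = {
            c: sum(1 for cr in crowd if cr.crowding_class == c)
            for c in ("higher", "lower", "not_different")}

    clefts = [r["cleft"] for r in results if r.get("cleft") is not None]
    if clefts:
        means = np.array([c.mean_height for c in clefts])
        weights = np.array([c.n_in_cleft for c in clefts], dtype=float)
        out["cleft_mean_of_means_nm"] = float(means.mean())
        out["cleft_pooled_mean_nm"] = float(
            np.average(means, weights=weights))
        out["cleft_min_nm"] = float(min(c.min_height for c in clefts))
        out["cleft_max_nm"] = float(max(c.max_height for c in clefts))

    reps = [r["clusters"] for r in results if r.get("clusters") is not None]
    if reps:
        counts = np.array([rep.n_clusters for rep in reps])
        sizes = np.concatenate([rep.sizes for rep in reps]) if any(
            rep.n_clusters for rep in reps) else np.zeros(0)
        out["cluster_count_distribution"] = {
            int(k): int(v) for k, v in
            zip(*np.unique(counts, return_counts=True))}
        out["mean_clusters_per_synapse"] = float(counts.mean())
        out["fraction_synapses_with_cluster"] = float((counts > 0).mean())
        out["fraction_synapses_with_non_cleft_cluster"] = float(np.mean([
            (rep.class_counts["boundary"] + rep.class_counts["perisynaptic"]) > 0
            for rep in reps]))
        if sizes.size:
            out["mean_receptors_per_cluster"] = float(sizes.mean())
            out["max_receptors_per_cluster"] = int(sizes.max())
    return out
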