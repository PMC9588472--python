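"""Posterior embedding extraction and degeneracy reporting.

After a fit, every participant-trial combination has an activation
embedding z^C = theta_C(z^P, z^S); its posterior mean is the network
applied to the posterior means, and its spread is the standard deviation
of pushforward draws from the embedding posteriors. Cluster structure of
those means is quantified with silhouette-selected k-means over a small
k range — a deterministic, auditable stand-in for reading cluster counts
off a scatter plot — and summarized in a degeneracy verdict:

* one experimental cluster apart from baseline -> ``non_degenerate``;
* clusters align with trial types, none split by participant ->
  ``by_condition``;
* any trial type whose combinations occupy participant-distinct
  clusters -> ``by_condition_and_participant``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .autodiff import Tensor
from .exceptions import ValidationError
from .inference import FitResult
from .simulate import Dataset


@dataclass(frozen=True)
class EmbeddingTable:
    """One row per combination (activation space) or participant (spatial)."""

    rows: pd.DataFrame  # participant_id, trial_id, trial_type, mean_*, std_*
    space: str          # "activation" | "spatial"

    @property
    def means(self) -> np.ndarray:
        cols = [c for c in self.rows.columns if c.startswith("mean_")]
        return self.rows[cols].to_numpy()


@dataclass(frozen=True)
class DegeneracyReport:
    chosen_k: int
    silhouette_by_k: dict
    cluster_assignments: list
    purity_by_trial_type: float
    participant_split_trials: list
    verdict: str

    def to_json(self, path=None, extra: dict | None = None) -> str:
        payload = asdict(self)
        payload["silhouette_by_k"] = {str(k): v for k, v
                                      in self.silhouette_by_k.items()}
        if extra:
            payload.update(extra)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def extract_embeddings(result: FitResult, dataset: Dataset,
                       space: str = "activation", seed: int = 0,
                       n_draws: int = 100) -> EmbeddingTable:
    """Posterior activation (or spatial) embeddings as a tidy table.

    Activation rows: theta_C applied to the posterior means of z^P and
    z^S per observed combination, with stds from ``n_draws`` pushforward
    samples. Spatial rows: posterior means/stds of z^PF per participant.
    """
    if result.epochs_run < 1:
        raise ValidationError("result is untrained; fit the model first")
    q = result.posterior
    D = q.dims["D"]
    if space == "spatial":
        rows = []
        for p in range(q.dims["P"]):
            rec = {"participant_id": p + 1, "trial_id": None, "trial_type": None}
            for d in range(D):
                rec[f"mean_{d}"] = q.mean["z_PF"].data[p, d]
                rec[f"std_{d}"] = q.std("z_PF")[p, d]
            rows.append(rec)
        return EmbeddingTable(rows=pd.DataFrame(rows), space="spatial")
    if space != "activation":
        raise ValidationError("space must be 'activation' or 'spatial'")

    rng = np.random.default_rng(seed)
    mu_P, sd_P = q.mean["z_P"].data, q.std("z_P")
    mu_S, sd_S = q.mean["z_S"].data, q.std("z_S")
    rows = []
    for seg in dataset.segments:
        p, s = seg.participant_id - 1, seg.trial_id - 1
        center = result.nets.combine(Tensor(mu_P[p]), Tensor(mu_S[s])).data
        draws_P = mu_P[p] + sd_P[p] * rng.standard_normal((n_draws, D))
        draws_S = mu_S[s] + sd_S[s] * rng.standard_normal((n_draws, D))
        pushed = result.nets.combine(Tensor(draws_P), Tensor(draws_S)).data
        std = pushed.std(axis=0)
        rec = {"participant_id": seg.participant_id, "trial_id": seg.trial_id,
               "trial_type": seg.trial_type}
        for d in range(D):
            rec[f"mean_{d}"] = center[d]
            rec[f"std_{d}"] = std[d]
        rows.append(rec)
    return EmbeddingTable(rows=pd.DataFrame(rows), space="activation")


SILHOUETTE_MARGIN = 0.02


def silhouette_select_k(means: np.ndarray, k_range=range(2, 7), seed: int = 0,
                        margin: float = SILHOUETTE_MARGIN):
    """Seeded k-means (20 restarts) per k; pick the silhouette argmax.

    Near-ties go to the smaller k: the chosen k is the smallest whose
    silhouette is within ``margin`` of the maximum (a parsimony rule —
    visually indistinguishable improvements never justify extra
    clusters). Returns (chosen_k, silhouette_by_k, assignments_by_k).
    """
    means = np.asarray(means, dtype=float)
    ks = sorted(k_range)
    if means.shape[0] < 3:
        raise ValidationError("need at least 3 points to cluster")
    if means.shape[0] < max(ks):
        ks = [k for k in ks if k < means.shape[0]]
    silhouette_by_k: dict[int, float] = {}
    assignments: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=20, random_state=seed).fit(means)
        labels = km.labels_
        if len(np.unique(labels)) < 2:
            silhouette_by_k[k] = -1.0
        else:
            silhouette_by_k[k] = float(silhouette_score(means, labels))
        assignments[k] = labels
    best = max(silhouette_by_k.values())
    chosen = min(k for k in ks if silhouette_by_k[k] >= best - margin)
    return chosen, silhouette_by_k, assignments


def _purity(assignments, labels) -> float:
    assignments = np.asarray(assignments)
    labels = np.asarray(labels)
    total = 0
    for c in np.unique(assignments):
        _, counts = np.unique(labels[assignments == c], return_counts=True)
        total += counts.max()
    return total / len(labels)


def degeneracy_verdict(table: EmbeddingTable, chosen_k: int,
                       assignments, silhouette_by_k=None) -> DegeneracyReport:
    """Apply the decision rule to clustered activation embeddings."""
    df = table.rows
    assignments = np.asarray(assignments)
    if len(assignments) != len(df):
        raise ValidationError("assignments must cover all combinations")
    trial_types = df["trial_type"].to_numpy()
    participants = df["participant_id"].to_numpy()
    is_exp = trial_types != "baseline"

    split_types = []
    for tt in pd.unique(trial_types[is_exp]):
        sel = trial_types == tt
        clusters = assignments[sel]
        if len(np.unique(clusters)) < 2:
            continue
        # split by participant: cluster membership perfectly predicted by ID
        mapping = {}
        perfect = True
        for c, p in zip(clusters, participants[sel]):
            if c in mapping and mapping[c] != p:
                perfect = False
                break
            mapping[c] = p
        if perfect and len(set(mapping.values())) > 1:
            split_types.append(str(tt))

    exp_clusters = set(assignments[is_exp])
    base_clusters = set(assignments[~is_exp])
    if split_types:
        verdict = "by_condition_and_participant"
    elif len(exp_clusters) == 1 and not (exp_clusters & base_clusters):
        verdict = "non_degenerate"
    else:
        verdict = "by_condition"

    return DegeneracyReport(
        chosen_k=int(chosen_k),
        silhouette_by_k=dict(silhouette_by_k or {}),
        cluster_assignments=[int(a) for a in assignments],
        purity_by_trial_type=float(_purity(assignments, trial_types)),
        participant_split_trials=sorted(split_types),
        verdict=verdict,
    )


def analyze(result: FitResult, dataset: Dataset, seed: int = 0,
            k_range=range(2, 7)):
    """Extract activation embeddings, cluster them, and report degeneracy."""
    table = extract_embeddings(result, dataset, seed=seed)
    chosen_k, sil, assignments = silhouette_select_k(
        table.means, k_range=k_range, seed=seed)
    report = degeneracy_verdict(table, chosen_k, assignments[chosen_k],
                                silhouette_by_k=sil)
    return table, report


def plot_embeddings(table: EmbeddingTable, path=None, ax=None):
    """2-D scatter: glyph by participant, color by trial type."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table.rows
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    markers = ["o", "^", "s", "D", "v", "P", "X", "*"]
    types = list(pd.unique(df["trial_type"]))
    cmap = plt.get_cmap("tab10")
    for _, row in df.iterrows():
        pid = int(row["participant_id"])
        color = cmap(types.index(row["trial_type"]) % 10)
        ax.errorbar(row["mean_0"], row["mean_1"],
                    xerr=row["std_0"], yerr=row["std_1"],
                    marker=markers[(pid - 1) % len(markers)],
                    color=color, capsize=2, linestyle="none")
    handles = [plt.Line2D([], [], marker="o", linestyle="none",
                          color=cmap(types.index(t) % 10), label=str(t))
               for t in types]
    ax.legend(handles=handles, fontsize=8)
    ax.set_xlabel("embedding dim 1")
    ax.set_ylabel("embedding dim 2")
    ax.set_title(f"{table.space} embeddings")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def write_table(table: EmbeddingTable, path) -> None:
    table.rows.to_csv(path, sep="\t", index=False)
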