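"""The probability of identical profiles (PIP) and shift-detection metrics.

From an MCMC trace, the posterior allocation probability of site n to
component k is the fraction of stored draws with z_n = k. Running the
sampler separately on two taxon partitions (a focal monophyletic
sub-clade and the remainder of the tree) yields two allocation tables;
the PIP at site n is the dot product of the two allocation vectors —
the posterior probability that the same component governed the site in
both partitions, under the crude assumption that the partitions are
independent. PIP is 1 when both partitions allocate fully to the same
component, 0 when allocations are entirely disjoint, and 0.5 when both
spread 50/50 over the same two components (the chance level of picking
the same profile twice). Sites with PIP at or below a cutoff (0.05 by
default) are flagged as candidate preference shifts; an optional
entropy filter can exclude sites whose low PIP merely reflects weak,
diffuse allocation rather than a clear shift.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mcmc import McmcTrace

DEFAULT_PIP_THRESHOLD = 0.05


@dataclass
class AllocationProbabilities:
    """N x K posterior allocation probabilities for one taxon partition."""

    table: np.ndarray
    partition_label: str = ""

    def __post_init__(self):
        t = np.asarray(self.table, dtype=float)
        if t.ndim != 2:
            raise ValueError("allocation table must be 2-D (sites x components)")
        if np.any(t < 0) or np.any(t > 1 + 1e-12):
            raise ValueError("allocation probabilities must lie in [0, 1]")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("allocation rows must sum to 1")
        self.table = t

    @property
    def n_sites(self) -> int:
        return self.table.shape[0]

    @property
    def K(self) -> int:
        return self.table.shape[1]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("site\t" + "\t".join(f"p{k+1}" for k in range(self.K)) + "\n")
            for n in range(self.n_sites):
                row = "\t".join(repr(float(v)) for v in self.table[n])
                fh.write(f"{n + 1}\t{row}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, partition_label: str = "") -> "AllocationProbabilities":
        df = pd.read_csv(path, sep="\t")
        cols = [c for c in df.columns if c.startswith("p")]
        return cls(df[cols].to_numpy(), partition_label=partition_label)


def allocation_probability(trace: McmcTrace, partition_label: str = "") -> AllocationProbabilities:
    """Posterior allocation frequencies p^(n)(k) from a trace.

    p^(n)(k) = (1/M) * #{draws m : z_n^(m) = k}.
    """
    if trace.n_draws < 1:
        raise ValueError("empty trace")
    M, N = trace.z.shape
    table = np.zeros((N, trace.K))
    for k in range(trace.K):
        table[:, k] = (trace.z == k).sum(axis=0) / M
    return AllocationProbabilities(table, partition_label=partition_label)


def pip(p_a: np.ndarray, p_b: np.ndarray) -> float:
    """Probability of identical profiles: sum_k p_a(k) * p_b(k)."""
    a = np.asarray(p_a, dtype=float)
    b = np.asarray(p_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("allocation vectors must have the same length")
    return float(a @ b)


def allocation_entropy(p: np.ndarray) -> float:
    """Shannon entropy (nats) of an allocation vector, with 0 log 0 = 0.

    Quantifies how diffusely a site is allocated: 0 for a point mass,
    ln K for a uniform spread over K components.
    """
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


@dataclass
class PipReport:
    """Per-site PIP scores, entropies, top components, and shift calls."""

    frame: pd.DataFrame
    threshold: float
    entropy_max: float | None = None

    @property
    def pip_values(self) -> np.ndarray:
        return self.frame["pip"].to_numpy()

    @property
    def called_sites(self) -> np.ndarray:
        """1-based site numbers flagged as shifts."""
        return self.frame.loc[self.frame["shift"], "site"].to_numpy()

    def write_tsv(self, path: str | Path) -> None:
        df = self.frame.copy()
        for col in ("pip", "entropy_a", "entropy_b", "top_prob_a", "top_prob_b"):
            df[col] = df[col].map(repr)
        df["shift"] = df["shift"].map(int)
        df.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        n = len(self.frame)
        called = int(self.frame["shift"].sum())
        lines = [
            "PIP shift report",
            f"  sites:            {n}",
            f"  PIP threshold:    <= {self.threshold}",
            f"  entropy filter:   "
            + (f"<= {self.entropy_max}" if self.entropy_max is not None else "off"),
            f"  flagged shifts:   {called}",
            f"  median PIP:       {np.median(self.pip_values):.4f}",
        ]
        return "\n".join(lines)


def classify_sites(
    probs_a: AllocationProbabilities,
    probs_b: AllocationProbabilities,
    threshold: float = DEFAULT_PIP_THRESHOLD,
    entropy_max: float | None = None,
) -> PipReport:
    """Score every site's PIP across two partitions and flag shifts.

    A site is flagged when PIP <= threshold (inclusive, matching the
    "from 0 to 0.05" convention). With ``entropy_max`` set, both
    partitions' allocation entropies must also be at most that value,
    filtering out sites whose low PIP comes from weak allocation.
    """
    if probs_a.n_sites != probs_b.n_sites or probs_a.K != probs_b.K:
        raise ValueError("allocation tables must have matching N and K")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    A, B = probs_a.table, probs_b.table
    pips = np.einsum("nk,nk->n", A, B)
    ent_a = np.array([allocation_entropy(r) for r in A])
    ent_b = np.array([allocation_entropy(r) for r in B])
    top_a = A.argmax(axis=1)
    top_b = B.argmax(axis=1)
    shift = pips <= threshold
    if entropy_max is not None:
        shift &= (ent_a <= entropy_max) & (ent_b <= entropy_max)
    frame = pd.DataFrame(
        {
            "site": np.arange(1, probs_a.n_sites + 1),
            "pip": pips,
            "entropy_a": ent_a,
            "entropy_b": ent_b,
            "top_a": top_a + 1,
            "top_prob_a": A[np.arange(A.shape[0]), top_a],
            "top_b": top_b + 1,
            "top_prob_b": B[np.arange(B.shape[0]), top_b],
            "shift": shift,
        }
    )
    return PipReport(frame=frame, threshold=threshold, entropy_max=entropy_max)


def confusion_metrics(calls: np.ndarray, truth: set[int], n_sites: int) -> dict:
    """TPR, FPR, precision and recall of shift calls against a truth set.

    ``calls`` and ``truth`` hold 1-based site numbers. TPR = TP/|truth|
    (NA when no true shifts exist), FPR = FP/(N - |truth|), precision =
    TP/(TP + FP) (0 when nothing is called).
    """
    call_set = set(int(c) for c in np.asarray(calls).ravel())
    truth = set(int(t) for t in truth)
    if not truth <= set(range(1, n_sites + 1)):
        raise ValueError("truth contains site numbers outside the alignment")
    tp = len(call_set & truth)
    fp = len(call_set - truth)
    n_null = n_sites - len(truth)
    tpr = tp / len(truth) if truth else float("nan")
    fpr = fp / n_null if n_null else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tpr
    return {"TPR": tpr, "FPR": fpr, "precision": precision, "recall": recall,
            "TP": tp, "FP": fp, "n_calls": len(call_set)}


def precision_recall_curve(
    pip_values: np.ndarray, truth: set[int]
) -> list[tuple[float, float, float]]:
    """Sweep PIP thresholds and report (threshold, precision, recall).

    Thresholds run over the sorted unique PIP values plus the endpoints
    0 and 1; a site is called at threshold t when its PIP <= t, so
    recall is non-decreasing in t.
    """
    pips = np.asarray(pip_values, dtype=float)
    n_sites = pips.size
    truth = set(int(t) for t in truth)
    thresholds = sorted(set(np.concatenate([[0.0, 1.0], np.unique(pips)])))
    out = []
    sites = np.arange(1, n_sites + 1)
    for t in thresholds:
        calls = sites[pips <= t]
        m = confusion_metrics(calls, truth, n_sites)
        out.append((float(t), m["precision"], m["recall"]))
    return out
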