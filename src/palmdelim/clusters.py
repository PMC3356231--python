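"""Genotypic-cluster criterion: ΔK, Q-matrix alignment, and membership rules.

Post-inference computations on Bayesian admixture output.  The number of
genetic groups K is chosen by the ΔK statistic -- the mean absolute second
difference of the log data probability LnP(K) across K, divided by the
standard deviation of LnP(K) over replicate runs, which peaks at the
strongest change of curvature.  Replicate membership (Q) matrices suffer
label switching across runs; a greedy CLUMPP-style alignment permutes each
replicate's cluster labels to best match the running average, with the
per-step optimum found exactly by solving a K x K assignment problem.  The
genotypic-cluster species criterion is then applied to the averaged Q
matrix: a putative species satisfies the necessary condition when the mean
membership of its individuals in their modal cluster exceeds a threshold
(0.8 by convention, configurable), and the sufficiency (exclusivity)
condition when no outside individual exceeds that threshold in the same
cluster.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .matrices import GroupingMap

__all__ = [
    "LnPTable",
    "DeltaKResult",
    "QReplicateSet",
    "GSCRecord",
    "AlignmentResult",
    "evanno_delta_k",
    "align_q_replicates",
    "gsc_report",
    "parse_structure_results",
    "read_lnp_tsv",
    "read_q_tsv",
]


@dataclass
class LnPTable:
    """Replicate LnP(K) values for a contiguous range of K."""

    values: dict  # K -> list of floats

    def __post_init__(self):
        ks = sorted(self.values)
        if not ks:
            raise ValueError("empty LnP table")
        if ks != list(range(ks[0], ks[-1] + 1)):
            raise ValueError("K range must be contiguous")
        for k, vals in self.values.items():
            if len(vals) < 1:
                raise ValueError(f"no replicates at K={k}")

    @property
    def ks(self):
        return sorted(self.values)


@dataclass
class DeltaKResult:
    ks: list
    mean: dict  # K -> mean LnP
    sd: dict  # K -> sample sd of LnP (nan if 1 replicate)
    l_prime: dict  # K -> L(K) - L(K-1), undefined at first K
    l_second: dict  # K -> |L''(K)|, undefined at endpoints
    delta_k: dict  # K -> ΔK or nan where undefined
    best_k: int  # argmax over defined ΔK entries

    def defined_ks(self):
        return [k for k in self.ks if np.isfinite(self.delta_k.get(k, np.nan))]


def evanno_delta_k(table: LnPTable, pairing: str = "by-replicate") -> DeltaKResult:
    """ΔK = mean|L''(K)| / sd(L(K)), maximized over interior K.

    ``by-replicate``: |L''(K)| is averaged over replicates paired by index,
    |L_r(K+1) - 2 L_r(K) + L_r(K-1)| (requires equal replicate counts per K);
    ``by-mean``: the absolute second difference of the per-K means.  ΔK is
    undefined at the range endpoints and wherever sd(L(K)) = 0; an all-
    undefined table is an error.
    """
    if pairing not in ("by-replicate", "by-mean"):
        raise ValueError(f"unknown pairing {pairing!r}")
    ks = table.ks
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    vals = {k: np.asarray(table.values[k], dtype=float) for k in ks}
    mean = {k: float(vals[k].mean()) for k in ks}
    sd = {
        k: float(vals[k].std(ddof=1)) if len(vals[k]) > 1 else float("nan")
        for k in ks
    }
    l_prime = {k: mean[k] - mean[k - 1] for k in ks[1:]}
    l_second = {}
    for k in ks[1:-1]:
        if pairing == "by-replicate":
            n = {len(vals[k - 1]), len(vals[k]), len(vals[k + 1])}
            if len(n) != 1:
                raise ValueError(
                    "by-replicate pairing needs equal replicate counts per K"
                )
            l_second[k] = float(
                np.abs(vals[k + 1] - 2 * vals[k] + vals[k - 1]).mean()
            )
        else:
            l_second[k] = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
    delta_k = {}
    for k in ks:
        if k in l_second and np.isfinite(sd[k]) and sd[k] > 0:
            delta_k[k] = l_second[k] / sd[k]
        else:
            delta_k[k] = float("nan")
    defined = [k for k in ks if np.isfinite(delta_k[k])]
    if not defined:
        raise ValueError("ΔK undefined at every K (sd = 0 or single replicates)")
    best_k = max(defined, key=lambda k: delta_k[k])
    return DeltaKResult(ks, mean, sd, l_prime, l_second, delta_k, best_k)


@dataclass
class QReplicateSet:
    """Replicate individuals x K membership matrices, shared ordering."""

    individuals: list
    replicates: list  # list of (N, K) arrays

    def __post_init__(self):
        if not self.replicates:
            raise ValueError("no replicates")
        n = len(self.individuals)
        k = self.replicates[0].shape[1]
        cleaned = []
        for i, rep in enumerate(self.replicates):
            rep = np.asarray(rep, dtype=float)
            if rep.shape != (n, k):
                raise ValueError(
                    f"replicate {i}: shape {rep.shape}, expected {(n, k)}"
                )
            if rep.min() < -1e-9 or rep.max() > 1 + 1e-9:
                raise ValueError(f"replicate {i}: coefficients outside [0, 1]")
            if not np.allclose(rep.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError(f"replicate {i}: rows do not sum to 1")
            cleaned.append(rep)
        self.replicates = cleaned

    @property
    def k(self) -> int:
        return self.replicates[0].shape[1]

    def __len__(self):
        return len(self.replicates)


@dataclass
class AlignmentResult:
    aligned: QReplicateSet
    mean_q: np.ndarray
    similarity: float
    permutations: list  # per replicate, tuple p with aligned[:, j] = rep[:, p[j]]


def _pairwise_similarity(reps) -> float:
    """Mean over pairs of 1 - ||A - B||_1 / (2N); 1 for identical sets."""
    n_ind = reps[0].shape[0]
    sims = []
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            d = np.abs(reps[i] - reps[j]).sum() / (2 * n_ind)
            sims.append(1.0 - d)
    return float(np.mean(sims)) if sims else 1.0


def align_q_replicates(
    reps: QReplicateSet, permutations: int = 1000, seed: int = 0
) -> AlignmentResult:
    """Greedy label alignment of replicate Q matrices.

    For each of ``permutations`` random replicate orderings, replicates are
    incorporated one at a time: the incoming replicate's cluster labels are
    permuted to best match the running mean, the per-step optimum found
    exactly by a K x K linear assignment minimizing the summed absolute
    coefficient differences.  The ordering with the highest final pairwise
    similarity wins; its per-replicate permutations are applied in the
    original replicate order and the aligned replicates averaged.
    """
    k = reps.k
    if k > 30:
        raise ValueError("K > 30 not supported")
    rng = np.random.default_rng(seed)
    r = len(reps)
    best = None
    n_orders = max(1, permutations)
    for trial in range(n_orders):
        order = rng.permutation(r) if trial else np.arange(r)
        perms = [None] * r
        first = order[0]
        perms[first] = tuple(range(k))
        running = reps.replicates[first].copy()
        count = 1
        for idx in order[1:]:
            rep = reps.replicates[idx]
            mean = running / count
            # cost[j, c] = L1 cost of assigning replicate column c to slot j
            cost = np.abs(mean[:, :, None] - rep[:, None, :]).sum(axis=0)
            rows, cols = linear_sum_assignment(cost)
            perm = tuple(cols[np.argsort(rows)])
            running = running + rep[:, list(perm)]
            perms[idx] = perm
            count += 1
        aligned = [
            reps.replicates[i][:, list(perms[i])] for i in range(r)
        ]
        sim = _pairwise_similarity(aligned)
        if best is None or sim > best[0] + 1e-12:
            best = (sim, perms, aligned)
    sim, perms, aligned = best
    mean_q = np.mean(aligned, axis=0)
    return AlignmentResult(
        aligned=QReplicateSet(list(reps.individuals), aligned),
        mean_q=mean_q,
        similarity=sim,
        permutations=perms,
    )


@dataclass
class GSCRecord:
    """Species-level genotypic-cluster summary against the averaged Q."""

    species: str
    modal_cluster: int = None  # 1-based cluster index, as printed
    mean_coefficient: float = None
    min_coefficient: float = None
    necessary: bool = None  # mean coefficient > high threshold
    exclusive: bool = None  # no outsider > high threshold in modal cluster
    n_intermediate: int = 0  # members with max coefficient in (low, high)
    modal_tie: bool = False
    assessed: bool = True

    @property
    def satisfied(self):
        """Necessary-and-sufficient: the species is its own exclusive cluster."""
        if not self.assessed:
            return None
        return bool(self.necessary and self.exclusive)

    def render(self) -> str:
        """Table-style cell, e.g. ``'12; 0.91'``."""
        if not self.assessed:
            return "-"
        return f"{self.modal_cluster}; {self.mean_coefficient:.2f}"


def gsc_report(
    mean_q: np.ndarray,
    individuals: list,
    grouping: GroupingMap,
    high: float = 0.8,
    low: float = 0.5,
) -> list:
    """Apply the genotypic-cluster membership rules per putative species.

    Modal cluster = argmax of the species' mean membership (ties to the
    lowest index, flagged); ``necessary`` iff that mean exceeds ``high``
    (strict); ``exclusive`` iff no individual outside the species has a
    coefficient above ``high`` in the modal cluster; intermediates are
    member individuals whose maximum coefficient lies strictly between
    ``low`` and ``high``.
    """
    mean_q = np.asarray(mean_q, dtype=float)
    if not np.allclose(mean_q.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("mean Q rows must sum to 1")
    idx_of = {ind: i for i, ind in enumerate(individuals)}
    by_species: dict = {}
    for ind in individuals:
        if ind in grouping.terminal_to_population:
            by_species.setdefault(grouping.species_of(ind), []).append(idx_of[ind])
    records = []
    for sp in grouping.species:
        rows = by_species.get(sp, [])
        if not rows:
            records.append(GSCRecord(species=sp, assessed=False))
            continue
        sub = mean_q[rows]
        means = sub.mean(axis=0)
        modal = int(np.argmax(means))
        tie = int(np.sum(np.isclose(means, means[modal]))) > 1
        mean_coeff = float(means[modal])
        min_coeff = float(sub[:, modal].min())
        outside = [i for i in range(len(individuals)) if i not in set(rows)]
        exclusive = not any(mean_q[i, modal] > high for i in outside)
        maxima = sub.max(axis=1)
        n_inter = int(np.sum((maxima > low) & (maxima < high)))
        records.append(
            GSCRecord(
                species=sp,
                modal_cluster=modal + 1,
                mean_coefficient=mean_coeff,
                min_coefficient=min_coeff,
                necessary=mean_coeff > high,
                exclusive=exclusive,
                n_intermediate=n_inter,
                modal_tie=tie,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Parsers


_LNP_RE = re.compile(r"Estimated Ln Prob of Data\s*=\s*(-?\d+(?:\.\d+)?)")


def parse_structure_results(text: str):
    """Parse a Structure-style results file.

    Extracts the estimated ln-probability line and the "Inferred ancestry of
    individuals" block, whose data lines look like::

        1 ind_1    (0)   1 :  0.912 0.088

    Returns ``(individuals, q_matrix, ln_prob)``; ``ln_prob`` is None when
    the line is absent.
    """
    m = _LNP_RE.search(text)
    ln_prob = float(m.group(1)) if m else None
    lines = text.splitlines()
    start = None
    for i, ln in enumerate(lines):
        if "Inferred ancestry of individuals" in ln:
            start = i + 1
            break
    if start is None:
        raise ValueError("no 'Inferred ancestry of individuals' block found")
    individuals, rows = [], []
    for ln in lines[start:]:
        s = ln.strip()
        if not s:
            if individuals:
                break
            continue
        if s.lower().startswith("label"):
            continue
        if ":" not in s:
            if individuals:
                break
            continue
        left, right = s.split(":", 1)
        parts = left.split()
        if len(parts) < 2:
            raise ValueError(f"malformed ancestry line: {ln!r}")
        individuals.append(parts[1])
        rows.append([float(x) for x in right.split()])
    if not individuals:
        raise ValueError("empty ancestry block")
    q = np.asarray(rows, dtype=float)
    return individuals, q, ln_prob


def read_lnp_tsv(source) -> LnPTable:
    """TSV with columns K, replicate, lnp (header required)."""
    import pandas as pd

    from .matrices import _as_path_or_buffer

    df = pd.read_csv(_as_path_or_buffer(source), sep="\t")
    for col in ("K", "lnp"):
        if col not in df.columns:
            raise ValueError(f"LnP table lacks column {col!r}")
    values: dict = {}
    for k, sub in df.groupby("K"):
        values[int(k)] = list(sub["lnp"].astype(float))
    return LnPTable(values)


def read_q_tsv(source) -> QReplicateSet:
    """TSV with columns replicate, individual, q1..qK (header required)."""
    import pandas as pd

    from .matrices import _as_path_or_buffer

    df = pd.read_csv(_as_path_or_buffer(source), sep="\t")
    qcols = [c for c in df.columns if re.fullmatch(r"q\d+", c)]
    qcols.sort(key=lambda c: int(c[1:]))
    if not qcols or "replicate" not in df.columns or "individual" not in df.columns:
        raise ValueError("Q table needs columns replicate, individual, q1..qK")
    reps = []
    individuals = None
    for _, sub in df.groupby("replicate"):
        inds = list(sub["individual"])
        if individuals is None:
            individuals = inds
        elif inds != individuals:
            raise ValueError("inconsistent individual lists across replicates")
        reps.append(sub[qcols].to_numpy(dtype=float))
    return QReplicateSet(individuals, reps)
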