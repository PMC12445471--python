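"""Synthetic cortical data with known ground truth.

Generates test meshes, contiguous parcellations, saturating-exponential
maturation truths, and measurement tables for a cross-sectional (human-like)
or longitudinal (macaque-like) study design.  Everything is seeded and
byte-reproducible; the draw order is documented in :func:`generate_dataset`.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .mesh import SurfaceMesh, make_icosphere

__all__ = [
    "StudyDesign",
    "TrajectoryTruth",
    "make_test_mesh",
    "assign_parcels",
    "make_inside_out_truth",
    "generate_dataset",
]


def make_test_mesh(subdivisions: int, radius: float) -> SurfaceMesh:
    """Icosphere fixture standing in for a cortical surface.

    Vertex count is ``10 * 4**subdivisions + 2``.
    """
    return make_icosphere(subdivisions, radius)


def assign_parcels(mesh: SurfaceMesh, n_parcels: int, seed: int) -> np.ndarray:
    """Label every vertex with a spatially contiguous parcel id in ``0..n_parcels-1``.

    Parcels are grown over the edge graph from seed vertices placed at the
    k-means centroids of the vertex coordinates; growth is a multi-source
    Dijkstra so each parcel is a connected graph-Voronoi cell.
    """
    n = mesh.n_vertices
    if not (1 <= n_parcels <= n):
        raise ValueError(f"n_parcels must be in [1, {n}], got {n_parcels}")
    if n_parcels == n:
        return np.arange(n, dtype=np.int64)
    if n_parcels == 1:
        return np.zeros(n, dtype=np.int64)

    km = KMeans(n_clusters=n_parcels, random_state=seed, n_init=4)
    km.fit(mesh.vertices)
    # one distinct seed vertex per centroid: greedy nearest unused vertex
    seeds = np.full(n_parcels, -1, dtype=np.int64)
    used = np.zeros(n, dtype=bool)
    for c in range(n_parcels):
        d = np.linalg.norm(mesh.vertices - km.cluster_centers_[c], axis=1)
        order = np.argsort(d, kind="stable")
        for v in order:
            if not used[v]:
                seeds[c] = v
                used[v] = True
                break

    graph = mesh.edge_graph()
    indptr, indices, weights = graph.indptr, graph.indices, graph.data
    labels = np.full(n, -1, dtype=np.int64)
    dist = np.full(n, np.inf)
    heap: list[tuple[float, int, int]] = []
    for c, s in enumerate(seeds):
        dist[s] = 0.0
        labels[s] = c
        heapq.heappush(heap, (0.0, int(s), c))
    while heap:
        d, v, c = heapq.heappop(heap)
        if d > dist[v]:
            continue
        for k in range(indptr[v], indptr[v + 1]):
            u = indices[k]
            nd = d + weights[k]
            if nd < dist[u]:
                dist[u] = nd
                labels[u] = c  # inherit from finalized parent -> contiguous cells
                heapq.heappush(heap, (nd, int(u), c))
    return labels


@dataclass
class StudyDesign:
    """Sampling design for one synthetic cohort."""

    mode: Literal["cross_sectional", "longitudinal"]
    n_subjects: int
    age_min: float
    age_max: float
    timepoints: int | None = None
    n_short_subjects: int = 0  # subjects receiving timepoints-1 visits
    sex_ratio: float = 0.5  # probability of male
    species: str = "human"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.age_max > self.age_min:
            raise ValueError("age range must have positive length")
        if self.mode == "longitudinal":
            if self.timepoints is None or self.timepoints < 2:
                raise ValueError("longitudinal mode requires timepoints >= 2")
            if self.n_short_subjects > self.n_subjects:
                raise ValueError("n_short_subjects exceeds n_subjects")
        elif self.mode != "cross_sectional":
            raise ValueError(f"unknown mode: {self.mode}")


@dataclass
class TrajectoryTruth:
    """Ground-truth saturating-exponential trajectories per (parcel, depth bin).

    The true curve is ``T(a) = B + A * (1 - exp(-r * (a - a0)))`` for
    ``a >= a0`` and ``B`` otherwise — non-decreasing whenever ``A >= 0`` and
    ``r > 0``.  The true plateau age is where the derivative
    ``A * r * exp(-r * (a - a0))`` crosses the threshold ``delta``.

    ``params`` is indexed by ``(parcel_id, depth_bin)`` with columns
    ``B, A, r, a0``.
    """

    params: pd.DataFrame
    sigma: float = 0.03
    sigma_b: float = 0.0
    beta_sex: float = 0.0
    delta: float | None = None

    def __post_init__(self) -> None:
        required = {"B", "A", "r", "a0"}
        if not required <= set(self.params.columns):
            raise ValueError(f"params must have columns {sorted(required)}")
        if (self.params["A"] < 0).any():
            raise ValueError("amplitude A must be >= 0")
        if (self.params["r"] <= 0).any():
            raise ValueError("rate r must be > 0")
        if self.sigma < 0 or self.sigma_b < 0:
            raise ValueError("noise sds must be >= 0")
        if self.delta is None:
            self.delta = max(self.sigma / 5.0, 1e-6)

    def _row(self, parcel, depth_bin) -> pd.Series:
        try:
            return self.params.loc[(parcel, depth_bin)]
        except KeyError:
            raise KeyError(f"unknown (parcel, depth_bin)=({parcel}, {depth_bin})")

    def value(self, parcel, depth_bin, age) -> np.ndarray | float:
        """True (noise-free) trajectory value at ``age`` (years)."""
        p = self._row(parcel, depth_bin)
        return true_trajectory(p["B"], p["A"], p["r"], p["a0"], age)

    def true_plateau(self, parcel, depth_bin) -> float:
        """Closed-form age at which the true derivative falls to ``delta``."""
        p = self._row(parcel, depth_bin)
        ar = p["A"] * p["r"]
        if ar > self.delta:
            return p["a0"] + np.log(ar / self.delta) / p["r"]
        return float(p["a0"])

    def to_json(self, path: str) -> None:
        payload = {
            "sigma": self.sigma,
            "sigma_b": self.sigma_b,
            "beta_sex": self.beta_sex,
            "delta": self.delta,
            "params": self.params.reset_index().to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "TrajectoryTruth":
        with open(path) as fh:
            payload = json.load(fh)
        params = pd.DataFrame(payload["params"]).set_index(["parcel_id", "depth_bin"])
        return cls(
            params=params,
            sigma=payload["sigma"],
            sigma_b=payload["sigma_b"],
            beta_sex=payload["beta_sex"],
            delta=payload["delta"],
        )


def true_trajectory(B, A, r, a0, age):
    """``B + A*(1 - exp(-r*(age - a0)))`` for ``age >= a0``, else ``B``."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    out = B + A * (1.0 - np.exp(-r * np.maximum(age - a0, 0.0)))
    return out if out.ndim else float(out)


def make_inside_out_truth(
    parcel_ids,
    sa_rank,
    depth_bins,
    *,
    baseline: float = 1.2,
    amplitude_fast: float = 0.42,
    amplitude_slow: float = 0.22,
    rate_fast: float = 0.30,
    rate_slow: float = 0.06,
    depth_rate_hi: float = 1.35,
    depth_rate_lo: float = 0.65,
    depth_amp_hi: float = 1.15,
    depth_amp_lo: float = 0.85,
    onset: float = 0.0,
    sigma: float = 0.03,
    sigma_b: float = 0.0,
    beta_sex: float = 0.02,
    delta: float | None = None,
) -> TrajectoryTruth:
    """Build a truth with the designed maturational gradients.

    Rates and amplitudes decrease with hierarchy rank (``sa_rank`` in [0, 1],
    0 = sensorimotor, 1 = association) and with superficiality (bin 1 = deepest
    gets ``depth_*_hi``), so that deep and sensorimotor trajectories are
    steeper with earlier plateaus — the inside-out + hierarchy structure.
    """
    parcel_ids = np.asarray(parcel_ids)
    sa_rank = np.asarray(sa_rank, dtype=float)
    if parcel_ids.shape != sa_rank.shape:
        raise ValueError("parcel_ids and sa_rank must align")
    depth_bins = list(depth_bins)
    nd = len(depth_bins)
    rows = []
    for pid, h in zip(parcel_ids, sa_rank):
        r_base = rate_fast + (rate_slow - rate_fast) * h
        a_base = amplitude_fast + (amplitude_slow - amplitude_fast) * h
        for j, db in enumerate(depth_bins):
            t = j / (nd - 1) if nd > 1 else 0.0  # 0 = deepest
            rf = depth_rate_hi + (depth_rate_lo - depth_rate_hi) * t
            af = depth_amp_hi + (depth_amp_lo - depth_amp_hi) * t
            rows.append(
                {
                    "parcel_id": pid,
                    "depth_bin": db,
                    "B": baseline,
                    "A": a_base * af,
                    "r": r_base * rf,
                    "a0": onset,
                }
            )
    params = pd.DataFrame(rows).set_index(["parcel_id", "depth_bin"])
    return TrajectoryTruth(
        params=params, sigma=sigma, sigma_b=sigma_b, beta_sex=beta_sex, delta=delta
    )


def generate_dataset(design: StudyDesign, truth: TrajectoryTruth) -> pd.DataFrame:
    """Simulate a long-format measurement table.

    One row per (subject, visit, parcel, depth_bin) with
    ``value = truth + beta_sex * [sex == M] + b_subject + noise``.

    Draw order under the single ``design.seed`` RNG (documented so
    regeneration is reproducible):

    1. subject sexes (Bernoulli ``sex_ratio``),
    2. subject random intercepts ``N(0, sigma_b^2)``,
    3. visit ages (uniform for cross-sectional; jittered per-subject grid
       for longitudinal),
    4. measurement noise ``N(0, sigma^2)`` for all rows in (subject, visit,
       parcel, depth) order.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_subjects
    sexes = np.where(rng.random(n) < design.sex_ratio, "M", "F")
    intercepts = rng.normal(0.0, truth.sigma_b, size=n)

    if design.mode == "cross_sectional":
        ages_per_subject = [
            np.array([a]) for a in rng.uniform(design.age_min, design.age_max, size=n)
        ]
    else:
        tp = design.timepoints
        span = design.age_max - design.age_min
        grid = np.linspace(design.age_min, design.age_max, tp)
        step = span / (tp - 1)
        ages_per_subject = []
        for i in range(n):
            jitter = rng.uniform(-0.15 * step, 0.15 * step, size=tp)
            ages = np.clip(grid + jitter, design.age_min, design.age_max)
            if i < design.n_short_subjects:
                drop = rng.integers(0, tp)
                ages = np.delete(ages, drop)
            ages_per_subject.append(np.sort(ages))

    cells = truth.params.index.to_frame(index=False)
    truth_vals = {
        (row.parcel_id, row.depth_bin): truth.params.loc[(row.parcel_id, row.depth_bin)]
        for row in cells.itertuples()
    }

    records = []
    for i in range(n):
        sid = f"sub-{i:04d}"
        sex_eff = truth.beta_sex if sexes[i] == "M" else 0.0
        for visit, age in enumerate(ages_per_subject[i], start=1):
            base = sex_eff + intercepts[i]
            for (pid, db), p in truth_vals.items():
                mu = true_trajectory(p["B"], p["A"], p["r"], p["a0"], age)
                records.append((sid, design.species, age, sexes[i], visit, pid, db, mu + base))
    table = pd.DataFrame.from_records(
        records,
        columns=[
            "subject_id", "species", "age", "sex", "visit", "parcel_id", "depth_bin", "value",
        ],
    )
    table["value"] = table["value"].to_numpy() + rng.normal(0.0, truth.sigma, size=len(table))
    return table
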