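"""Synthetic ground-truth networks and BOLD-like cohorts.

The generator emulates the shape of a resting-state ROI study — per subject a
t×n time-series matrix (defaults 170×116) drawn from a zero-mean multivariate
normal whose covariance Σ = W_true + δI is a diagonally-loaded ground-truth
network, plus independent Gaussian observation noise.  Sampling is i.i.d. in
time by default: every estimator in this package is a function of the sample
covariance only, so temporal autocorrelation would add realism without adding
test power.  An AR(1) option (which preserves the stationary covariance) is
available for experiments that want serial dependence.

Two-group cohorts inject a fixed effect on a known set of differential edges
in the positive group, with a common diagonal loading for both groups so that
the group difference is confined to those edges.  Everything is a pure
function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .io_formats import CohortEntry, CohortManifest, TimeSeriesMatrix, write_cohort_manifest, write_timeseries

__all__ = [
    "GroundTruthNetwork",
    "SyntheticCohort",
    "make_ground_truth",
    "simulate_timeseries",
    "population_correlation",
    "make_cohort",
    "write_cohort",
]

#: Default study-scale conditions: 170 time points × 116 ROIs, 45/47 subjects.
DEFAULT_T = 170
DEFAULT_N = 116
DEFAULT_NOISE_SD = 0.2
#: Smallest eigenvalue enforced for Σ by diagonal loading; keeps Σ well
#: conditioned so population correlations are stable oracles.
MIN_EIGENVALUE = 0.1


@dataclass
class GroundTruthNetwork:
    W_true: np.ndarray
    topology: str  # "random_sparse" or "hub"
    hub_nodes: tuple[int, ...] = ()
    density: float = 0.0
    seed: int = 0

    @property
    def n(self) -> int:
        return self.W_true.shape[0]


@dataclass
class SyntheticCohort:
    subjects: list[tuple[TimeSeriesMatrix, str]]
    base_net: GroundTruthNetwork
    positive_net: GroundTruthNetwork
    differential_edges: tuple[tuple[int, int], ...]
    effect: float
    noise_sd: float
    seed: int
    delta: float = 0.0  # common diagonal loading used for both groups

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def labels(self) -> list[str]:
        return [lab for _, lab in self.subjects]


def make_ground_truth(
    n: int = DEFAULT_N,
    topology: str = "random_sparse",
    density: float = 0.05,
    hub_count: int = 8,
    hub_degree_multiplier: float = 4.0,
    weight_range: tuple[float, float] = (0.2, 0.8),
    seed: int = 0,
) -> GroundTruthNetwork:
    """Random symmetric zero-diagonal ground-truth network.

    ``random_sparse`` places edges independently at the given density with
    weights uniform in ±[weight_range]; ``hub`` boosts the edge probability
    of pairs touching one of ``hub_count`` designated hub nodes by
    ``hub_degree_multiplier`` (the base probability is deflated so overall
    density stays ≈ the requested value), producing a heavy-tailed degree
    sequence.
    """
    if not (0.0 < density < 1.0):
        raise ParameterError("density must lie in (0, 1)")
    if topology not in ("random_sparse", "hub"):
        raise ParameterError(f"unknown topology {topology!r}")
    if topology == "hub" and not (0 < hub_count < n):
        raise ParameterError("hub_count must lie in (0, n)")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    npairs = iu.size
    if topology == "random_sparse":
        prob = np.full(npairs, density)
        hubs: tuple[int, ...] = ()
    else:
        hub_idx = rng.choice(n, size=hub_count, replace=False)
        hubs = tuple(sorted(int(h) for h in hub_idx))
        touches = np.isin(iu, hub_idx) | np.isin(ju, hub_idx)
        frac = touches.mean()
        p0 = density / ((1 - frac) + hub_degree_multiplier * frac)
        prob = np.where(touches, min(1.0, hub_degree_multiplier * p0), p0)
    support = rng.random(npairs) < prob
    lo, hi = weight_range
    weights = rng.uniform(lo, hi, size=npairs) * rng.choice([-1.0, 1.0], size=npairs)
    vals = np.where(support, weights, 0.0)
    W = np.zeros((n, n))
    W[iu, ju] = vals
    W = W + W.T
    return GroundTruthNetwork(
        W_true=W, topology=topology, hub_nodes=hubs, density=density, seed=seed
    )


def _loading(W: np.ndarray, min_eig: float = MIN_EIGENVALUE) -> float:
    lam_min = float(np.linalg.eigvalsh(W)[0])
    return max(min_eig - lam_min, 0.0)


def _sigma(net: GroundTruthNetwork, delta: float | None = None) -> np.ndarray:
    W = net.W_true
    if delta is None:
        delta = _loading(W)
    return W + delta * np.eye(W.shape[0])


def population_correlation(
    net: GroundTruthNetwork, noise_sd: float = 0.0, delta: float | None = None
) -> np.ndarray:
    """Closed-form correlation of the generated signal (incl. observation noise)."""
    Sigma = _sigma(net, delta) + noise_sd**2 * np.eye(net.n)
    d = np.sqrt(np.diag(Sigma))
    return Sigma / np.outer(d, d)


def simulate_timeseries(
    net: GroundTruthNetwork,
    t: int = DEFAULT_T,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    ar_coeff: float = 0.0,
    delta: float | None = None,
    subject_id: str = "",
) -> TimeSeriesMatrix:
    """Draw t samples from N(0, W_true + δI) plus N(0, noise_sd²) noise.

    δ is chosen so the smallest eigenvalue of the loaded covariance is at
    least ``MIN_EIGENVALUE`` (or passed explicitly, e.g. a cohort-wide
    value).  With ``ar_coeff`` ρ > 0 the latent signal follows an AR(1)
    whose stationary covariance is still Σ.
    """
    if t < 2:
        raise ParameterError("need at least 2 time points")
    if not (0.0 <= ar_coeff < 1.0):
        raise ParameterError("ar_coeff must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    Sigma = _sigma(net, delta)
    L = np.linalg.cholesky(Sigma)
    z = rng.standard_normal((t, net.n))
    if ar_coeff > 0.0:
        innov_scale = np.sqrt(1.0 - ar_coeff**2)
        for k in range(1, t):
            z[k] = ar_coeff * z[k - 1] + innov_scale * z[k]
    X = z @ L.T
    if noise_sd > 0.0:
        X = X + noise_sd * rng.standard_normal((t, net.n))
    return TimeSeriesMatrix(values=X, subject_id=subject_id or f"sim_{seed}")


def make_cohort(
    n_pos: int = 45,
    n_neg: int = 47,
    base_net: GroundTruthNetwork | None = None,
    differential_edges: int = 30,
    effect: float = 0.4,
    t: int = DEFAULT_T,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    ar_coeff: float = 0.0,
    max_delta: float = 10.0,
) -> SyntheticCohort:
    """Two-group cohort with a known set of group-differential edges.

    The negative group is simulated from ``base_net``; the positive group
    from a copy with ``effect`` added to ``differential_edges`` randomly
    chosen node pairs.  A single diagonal loading δ (the larger of the two
    groups' requirements) is used for both Σ's, so the only systematic group
    difference is at the injected edges.  If the required δ exceeds
    ``max_delta`` the effect is considered to have broken positive
    definiteness beyond reasonable re-conditioning and an error is raised.
    """
    rng = np.random.default_rng(seed)
    if base_net is None:
        base_net = make_ground_truth(seed=int(rng.integers(2**31)))
    n = base_net.n
    iu, ju = np.triu_indices(n, k=1)
    if differential_edges > iu.size:
        raise ParameterError("more differential edges than node pairs")
    pick = rng.choice(iu.size, size=differential_edges, replace=False)
    pairs = tuple((int(iu[k]), int(ju[k])) for k in sorted(pick))
    W_pos = base_net.W_true.copy()
    for i, j in pairs:
        W_pos[i, j] += effect
        W_pos[j, i] += effect
    pos_net = GroundTruthNetwork(
        W_true=W_pos,
        topology=base_net.topology,
        hub_nodes=base_net.hub_nodes,
        density=base_net.density,
        seed=base_net.seed,
    )
    delta = max(_loading(base_net.W_true), _loading(W_pos))
    if delta > max_delta:
        raise ParameterError(
            f"injected effect requires diagonal loading δ={delta:.3g} > "
            f"{max_delta}; the perturbed network is too far from positive "
            "definite"
        )
    seeds = np.random.SeedSequence(seed).generate_state(n_pos + n_neg) % (2**31)
    subjects: list[tuple[TimeSeriesMatrix, str]] = []
    for k in range(n_pos):
        ts = simulate_timeseries(
            pos_net, t=t, noise_sd=noise_sd, seed=int(seeds[k]),
            ar_coeff=ar_coeff, delta=delta, subject_id=f"pos_{k + 1:03d}",
        )
        subjects.append((ts, "positive"))
    for k in range(n_neg):
        ts = simulate_timeseries(
            base_net, t=t, noise_sd=noise_sd, seed=int(seeds[n_pos + k]),
            ar_coeff=ar_coeff, delta=delta, subject_id=f"neg_{k + 1:03d}",
        )
        subjects.append((ts, "negative"))
    return SyntheticCohort(
        subjects=subjects,
        base_net=base_net,
        positive_net=pos_net,
        differential_edges=pairs,
        effect=effect,
        noise_sd=noise_sd,
        seed=seed,
        delta=delta,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str) -> str:
    """Write per-subject TSV files plus a manifest; returns the manifest path."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    entries = []
    for ts, label in cohort.subjects:
        fname = f"{ts.subject_id}.tsv"
        write_timeseries(ts, os.path.join(out_dir, fname))
        entries.append(CohortEntry(ts.subject_id, fname, label))
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    write_cohort_manifest(CohortManifest(entries), manifest_path)
    return manifest_path
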