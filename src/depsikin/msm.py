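"""Conformational-kinetics pipeline: dihedral features -> TICA -> CNN
clustering -> reversible Markov state model -> validation.

The stages mirror the standard MSM workflow for small-molecule MD:

1. backbone dihedral angles are embedded on the circle (sin/cos pairs),
2. time-lagged independent component analysis (TICA) finds the slowest
   linear coordinates at a chosen lag,
3. common-nearest-neighbor (CNN) density clustering defines core states and
   discards a low-density fraction of frames as noise,
4. transitions are counted with a sliding window (noise frames break the
   chain), the largest strongly connected state set is kept, and a
   transition matrix is estimated by reversible (detailed-balance
   constrained) maximum likelihood,
5. implied timescales across lags, a Chapman-Kolmogorov test, and -- for
   molecules whose symmetric conformer has a C2 axis -- a symmetry-based
   population diagnostic validate the model.  The symmetry diagnostic
   exploits that C2-equivalent states must have identical equilibrium
   populations, so any discrepancy directly measures sampling
   non-convergence.

Uncertainty bands come from trajectory-level bootstrap rather than a
Bayesian transition-matrix sampler: the same scientific role (error bands
for timescales and CK curves) with far simpler, fully testable machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import DepsikinError, DimensionError

__all__ = [
    "FeatureTrajectory",
    "TicaModel",
    "ClusterModel",
    "MarkovModel",
    "embed_dihedrals",
    "tica",
    "cnn_cluster",
    "count_transitions",
    "largest_connected_set",
    "ActiveSet",
    "estimate_reversible_msm",
    "implied_timescales",
    "ImpliedTimescales",
    "ck_test",
    "CKTestResult",
    "symmetry_diagnostic",
    "SymmetryPairDiagnostic",
    "lag_ns_to_frames",
    "NOISE_LABEL",
]

NOISE_LABEL = -1


@dataclass(frozen=True)
class FeatureTrajectory:
    """Time-ordered feature matrix (n_frames x n_features) with frame spacing dt (ns)."""

    frames: np.ndarray
    dt: float
    trajectory_id: str = "traj"
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, float)
        object.__setattr__(self, "frames", f)
        if f.ndim != 2 or f.shape[0] < 2:
            raise DimensionError(
                f"trajectory {self.trajectory_id!r} needs a 2D array with >= 2 frames, got {f.shape}"
            )
        if not self.dt > 0:
            raise DimensionError(f"dt must be > 0, got {self.dt}")

    def __len__(self) -> int:
        return self.frames.shape[0]


def embed_dihedrals(
    angles_deg: np.ndarray, dt: float, trajectory_id: str = "traj"
) -> FeatureTrajectory:
    """Map dihedral angles (degrees, in (-180, 180]) to interleaved (sin, cos) pairs.

    Doubles the feature count and removes the periodic discontinuity;
    invertible up to angle wrapping via atan2.
    """
    a = np.asarray(angles_deg, float)
    if a.ndim != 2:
        raise DimensionError(f"angle array must be 2D (frames x dihedrals), got {a.shape}")
    if np.any(a <= -180.0) or np.any(a > 180.0):
        raise DimensionError("angles must lie within (-180, 180] degrees")
    rad = np.deg2rad(a)
    out = np.empty((a.shape[0], 2 * a.shape[1]))
    out[:, 0::2] = np.sin(rad)
    out[:, 1::2] = np.cos(rad)
    return FeatureTrajectory(out, dt, trajectory_id)


def lag_ns_to_frames(lag_ns: float, dt_ns: float, tol: float = 1e-9) -> int:
    """Convert a physical lag to frames; non-integer multiples are an error."""
    frames = lag_ns / dt_ns
    if abs(frames - round(frames)) > tol:
        raise DimensionError(
            f"lag {lag_ns} ns is not an integer multiple of the frame spacing {dt_ns} ns"
        )
    n = int(round(frames))
    if n < 1:
        raise DimensionError(f"lag {lag_ns} ns is below one frame ({dt_ns} ns)")
    return n


# ---------------------------------------------------------------------------
# TICA

@dataclass
class TicaModel:
    """Solution of the symmetrized generalized eigenproblem C(tau) v = lambda C(0) v."""

    lag: int
    mean: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_components: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project mean-free data onto the retained components."""
        X = np.atleast_2d(np.asarray(X, float))
        return (X - self.mean) @ self.eigenvectors[:, : self.n_components]

    @property
    def kinetic_variance_fraction(self) -> np.ndarray:
        lam2 = np.clip(self.eigenvalues, 0.0, None) ** 2
        tot = lam2.sum()
        return lam2 / tot if tot > 0 else lam2


def tica(
    trajs: list[FeatureTrajectory],
    lag: int,
    n_components: int | None = None,
    ridge: float = 1e-10,
    kinetic_variance: float = 0.95,
) -> TicaModel:
    """Time-lagged independent component analysis over one or more trajectories.

    Covariances are symmetrized (the time-reversed pairs are averaged in),
    estimated with a single global mean over all frames that enter a lagged
    pair.  ``ridge`` (relative to the mean variance) regularizes C(0).  If
    ``n_components`` is None, enough components are kept to explain
    ``kinetic_variance`` of the total kinetic variance (sum of squared
    eigenvalues).
    """
    if lag < 1:
        raise DimensionError(f"lag must be >= 1 frame, got {lag}")
    for t in trajs:
        if len(t) <= lag:
            raise DimensionError(
                f"trajectory {t.trajectory_id!r} has {len(t)} frames, needs > lag = {lag}"
            )
    dim = trajs[0].frames.shape[1]

    # global mean over all frames entering a lagged pair
    total = np.zeros(dim)
    count = 0
    for t in trajs:
        x = t.frames
        total += x[:-lag].sum(axis=0) + x[lag:].sum(axis=0)
        count += 2 * (len(t) - lag)
    mean = total / count

    C0 = np.zeros((dim, dim))
    Ct = np.zeros((dim, dim))
    for t in trajs:
        x0 = t.frames[:-lag] - mean
        xt = t.frames[lag:] - mean
        C0 += x0.T @ x0 + xt.T @ xt
        Ct += x0.T @ xt + xt.T @ x0
    C0 /= count
    Ct /= count

    C0_reg = C0 + ridge * max(np.trace(C0) / dim, 1.0) * np.eye(dim)
    try:
        evals, evecs = scipy.linalg.eigh(Ct, C0_reg)
    except scipy.linalg.LinAlgError as exc:
        raise DepsikinError(
            "C(0) is singular even after ridge regularization; features are "
            "linearly dependent -- drop redundant dihedrals or raise the ridge"
        ) from exc
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    if n_components is None:
        frac = np.cumsum(np.clip(evals, 0.0, None) ** 2)
        tot = frac[-1]
        if tot <= 0:
            n_components = 1
        else:
            n_components = int(np.searchsorted(frac / tot, kinetic_variance) + 1)
            n_components = min(n_components, dim)
    if not 1 <= n_components <= dim:
        raise DimensionError(f"n_components must be in [1, {dim}], got {n_components}")
    return TicaModel(lag, mean, evals, evecs, n_components)


# ---------------------------------------------------------------------------
# CNN clustering

@dataclass
class ClusterModel:
    """Common-nearest-neighbor clustering result.

    ``labels`` holds one integer per point; ``NOISE_LABEL`` (-1) marks
    discarded low-density points, the remaining labels are contiguous
    integers ordered by decreasing cluster size.
    """

    cutoff_distance: float
    similarity: int
    noise_fraction: float
    labels: np.ndarray
    n_clusters: int

    def assign(self, points: np.ndarray, centers: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _cnn_edges(pts: np.ndarray, cutoff: float, similarity: int):
    """Edge list of the density-connectivity graph among retained points.

    An edge joins two points within ``cutoff`` that share at least
    ``similarity`` neighbors (within ``cutoff``, self excluded).  For
    moderate point counts a dense boolean adjacency with a BLAS matrix
    product counts common neighbors; for larger sets the sorted
    neighbor-array intersection keeps memory proportional to the pair list.
    """
    m = len(pts)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size == 0:
        return np.empty(0, int), np.empty(0, int)
    if m <= 4000:
        adj = np.zeros((m, m), dtype=np.float32)
        adj[pairs[:, 0], pairs[:, 1]] = 1.0
        adj += adj.T
        common = adj @ adj  # (i, j) entry: number of shared neighbors
        ok = common[pairs[:, 0], pairs[:, 1]] >= similarity
        return pairs[ok, 0], pairs[ok, 1]
    nbr = [[] for _ in range(m)]
    for i, j in pairs:
        nbr[i].append(j)
        nbr[j].append(i)
    nbr = [np.sort(np.asarray(v)) for v in nbr]
    rows, cols = [], []
    for i, j in pairs:
        if len(np.intersect1d(nbr[i], nbr[j], assume_unique=True)) >= similarity:
            rows.append(i)
            cols.append(j)
    return np.asarray(rows, int), np.asarray(cols, int)


def cnn_cluster(
    points: np.ndarray,
    cutoff: float,
    similarity: int,
    target_noise_fraction: float = 0.2,
) -> ClusterModel:
    """Density-based clustering by common nearest neighbors.

    The lowest-density ``target_noise_fraction`` of points (ranked by
    neighbor count within ``cutoff``) is discarded as noise first.  Two
    retained points are then density-connected iff their distance is at most
    ``cutoff`` *and* they share at least ``similarity`` common neighbors
    (neighborhoods evaluated among retained points); clusters are the
    connected components of that relation.  Deterministic and invariant
    under permutations of the point order (up to label identity).
    """
    pts = np.asarray(points, float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if cutoff <= 0:
        raise DimensionError(f"cutoff must be > 0, got {cutoff}")
    if similarity < 1:
        raise DimensionError(f"similarity must be >= 1, got {similarity}")
    if not 0 <= target_noise_fraction < 1:
        raise DimensionError("target_noise_fraction must be in [0, 1)")
    if n < similarity + 1:
        raise DimensionError(f"need at least similarity+1 = {similarity + 1} points, got {n}")

    tree = cKDTree(pts)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    density = np.bincount(pairs.ravel(), minlength=n)

    n_noise = int(np.floor(target_noise_fraction * n))
    # lowest density first; ties broken by the point coordinates themselves so
    # the noise set does not depend on the input order
    order = np.lexsort(tuple(pts[:, k] for k in reversed(range(pts.shape[1]))) + (density,))
    noise_idx = set(order[:n_noise].tolist())
    keep = np.array([i for i in range(n) if i not in noise_idx])

    labels = np.full(n, NOISE_LABEL, dtype=int)
    if keep.size:
        m = keep.size
        rows, cols = _cnn_edges(pts[keep], cutoff, similarity)
        graph = scipy.sparse.coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(m, m)
        )
        n_comp, comp = connected_components(graph, directed=False)
        # relabel by decreasing size; ties broken by smallest member index
        sizes = np.bincount(comp, minlength=n_comp)
        first = np.full(n_comp, m)
        for i, c in enumerate(comp):
            first[c] = min(first[c], i)
        rank = sorted(range(n_comp), key=lambda c: (-sizes[c], first[c]))
        remap = {c: r for r, c in enumerate(rank)}
        labels[keep] = [remap[c] for c in comp]
        n_clusters = n_comp
    else:
        n_clusters = 0
    return ClusterModel(
        cutoff_distance=cutoff,
        similarity=similarity,
        noise_fraction=float(np.mean(labels == NOISE_LABEL)),
        labels=labels,
        n_clusters=n_clusters,
    )


# ---------------------------------------------------------------------------
# counting and connectivity

def count_transitions(
    dtrajs: list[np.ndarray] | np.ndarray, lag: int, n_states: int | None = None
) -> np.ndarray:
    """Sliding-window transition counts; noise labels break the chain.

    ``C[i, j]`` counts frame pairs ``(t, t + lag)`` observed in states
    ``(i, j)``.  Pairs with a noise label (< 0) at either end contribute
    nothing -- noise frames are treated as gaps, not imputed.
    """
    if lag < 1:
        raise DimensionError(f"lag must be >= 1, got {lag}")
    if isinstance(dtrajs, np.ndarray) and dtrajs.ndim == 1:
        dtrajs = [dtrajs]
    arrs = [np.asarray(d, dtype=int) for d in dtrajs]
    if n_states is None:
        mx = max((int(a.max()) for a in arrs if a.size), default=-1)
        n_states = mx + 1
    C = np.zeros((n_states, n_states), dtype=np.int64)
    for a in arrs:
        if a.size <= lag:
            continue
        src, dst = a[:-lag], a[lag:]
        ok = (src >= 0) & (dst >= 0)
        np.add.at(C, (src[ok], dst[ok]), 1)
    return C


@dataclass(frozen=True)
class ActiveSet:
    """Largest strongly connected state set plus what was discarded."""

    states: tuple[int, ...]
    discarded: tuple[int, ...]
    provenance: dict[int, tuple[str, ...]] = field(default_factory=dict)

    def submatrix(self, counts: np.ndarray) -> np.ndarray:
        idx = np.asarray(self.states)
        return counts[np.ix_(idx, idx)]


def largest_connected_set(
    counts: np.ndarray, dtraj_labels=None, dtraj_ids=None
) -> ActiveSet:
    """Strongly connected component carrying the most transition counts.

    States outside it are discarded (they cannot support an ergodic Markov
    model); if discrete trajectories and their ids are supplied, the result
    records which trajectories visited each discarded state, so that e.g. a
    subset populated by a single simulation can be recognised as noise.
    """
    C = np.asarray(counts)
    n = C.shape[0]
    if n == 0:
        return ActiveSet((), ())
    visited = np.where(C.sum(axis=0) + C.sum(axis=1) > 0)[0]
    graph = scipy.sparse.csr_matrix((C > 0).astype(np.int8))
    n_comp, comp = connected_components(graph, directed=True, connection="strong")
    weights = np.zeros(n_comp)
    for c in range(n_comp):
        idx = np.where(comp == c)[0]
        weights[c] = C[np.ix_(idx, idx)].sum()
    # prefer the component with the most counts; tie-break by size then index
    sizes = np.bincount(comp, minlength=n_comp)
    best = max(range(n_comp), key=lambda c: (weights[c], sizes[c], -np.min(np.where(comp == c)[0])))
    states = tuple(int(i) for i in np.where(comp == best)[0])
    discarded = tuple(int(i) for i in visited if comp[i] != best)

    provenance: dict[int, tuple[str, ...]] = {}
    if dtraj_labels is not None:
        ids = dtraj_ids or [f"traj{k}" for k in range(len(dtraj_labels))]
        for s in discarded:
            provenance[s] = tuple(
                tid for tid, d in zip(ids, dtraj_labels) if np.any(np.asarray(d) == s)
            )
    return ActiveSet(states, discarded, provenance)


# ---------------------------------------------------------------------------
# reversible MSM

@dataclass
class MarkovModel:
    """Reversible Markov state model at a fixed lag.

    Invariants (asserted at construction): rows of the transition matrix
    sum to 1, the stationary distribution is normalized and satisfies
    pi T = pi, and detailed balance pi_i T_ij = pi_j T_ji holds.
    """

    lag: int
    active_set: tuple[int, ...]
    count_matrix: np.ndarray
    transition_matrix: np.ndarray
    stationary_distribution: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        T = self.transition_matrix
        pi = self.stationary_distribution
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise DepsikinError("transition matrix rows do not sum to 1")
        if not np.isclose(pi.sum(), 1.0, atol=1e-10):
            raise DepsikinError("stationary distribution does not sum to 1")
        if not np.allclose(pi @ T, pi, atol=1e-10):
            raise DepsikinError("stationary distribution is not invariant under T")
        flux = pi[:, None] * T
        if not np.allclose(flux, flux.T, atol=1e-10):
            raise DepsikinError("detailed balance violated")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def eigenvalues(self) -> np.ndarray:
        """Real spectrum of the reversible transition matrix, descending."""
        pi = self.stationary_distribution
        s = np.sqrt(pi)
        sym = self.transition_matrix * (s[:, None] / s[None, :])
        evals = np.linalg.eigvalsh(0.5 * (sym + sym.T))
        return np.sort(evals)[::-1]

    def timescales(self, n: int | None = None) -> np.ndarray:
        """Implied timescales -tau*dt / ln(lambda_i), i >= 2, in units of dt."""
        evals = self.eigenvalues()[1:]
        if n is not None:
            if n > len(evals):
                raise DimensionError(
                    f"requested {n} timescales but model has {self.n_states} states"
                )
            evals = evals[:n]
        out = np.full(len(evals), np.nan)
        pos = (evals > 0) & (evals < 1)
        out[pos] = -self.lag * self.dt / np.log(evals[pos])
        return out


def estimate_reversible_msm(
    counts: np.ndarray,
    lag: int = 1,
    dt: float = 1.0,
    active_set: tuple[int, ...] | None = None,
    tol: float = 1e-12,
    max_sweeps: int = 1_000_000,
) -> MarkovModel:
    """Maximum-likelihood transition matrix under detailed balance.

    Maximizes ``prod T_ij^{C_ij}`` over reversible row-stochastic matrices
    by the classic self-consistent iteration on the symmetric flux variables
    ``x_ij``::

        x_ij <- (C_ij + C_ji) / (c_i / x_i + c_j / x_j)

    iterated until the largest change falls below ``tol`` (or ``max_sweeps``
    sweeps).  For already-symmetric count matrices the fixed point is the
    row-normalized count matrix.  The stationary distribution is read off
    the converged fluxes.  ``counts`` must be strongly connected (apply
    ``largest_connected_set`` first).
    """
    C = np.asarray(counts, float)
    n = C.shape[0]
    if n == 0:
        raise DepsikinError("empty active set: no states to estimate")
    c = C.sum(axis=1)
    if np.any(c <= 0):
        raise DepsikinError(
            "every state needs outgoing counts; restrict to the largest connected set first"
        )
    Csym = C + C.T
    if np.any((Csym.sum(axis=1) - np.diag(Csym)) <= 0) and n > 1:
        raise DepsikinError("a state has no exchange counts; counts are not connected")

    x = Csym / Csym.sum()
    for _ in range(max_sweeps):
        xi = x.sum(axis=1)
        denom = c[:, None] / xi[:, None] + c[None, :] / xi[None, :]
        x_new = np.where(Csym > 0, Csym / denom, 0.0)
        x_new /= x_new.sum()
        delta = np.max(np.abs(x_new - x))
        x = x_new
        if delta < tol:
            break
    xi = x.sum(axis=1)
    T = x / xi[:, None]
    # clean numerical residue so the typed invariants hold exactly
    T = np.clip(T, 0.0, None)
    T /= T.sum(axis=1, keepdims=True)
    pi = xi / xi.sum()
    return MarkovModel(
        lag=lag,
        active_set=tuple(active_set) if active_set is not None else tuple(range(n)),
        count_matrix=np.asarray(counts),
        transition_matrix=T,
        stationary_distribution=pi,
        dt=dt,
    )


# ---------------------------------------------------------------------------
# implied timescales

@dataclass
class ImpliedTimescales:
    """Implied-timescale table t_i(tau) = -tau*dt / ln lambda_i(tau)."""

    lags: np.ndarray
    timescales: np.ndarray  # (n_lags, n_timescales), units of dt
    lower: np.ndarray | None = None  # 2.5% bootstrap band
    upper: np.ndarray | None = None  # 97.5% bootstrap band
    n_bootstrap: int = 0


def _its_single(dtrajs, lag, n_timescales, dt):
    C = count_transitions(dtrajs, lag)
    active = largest_connected_set(C)
    sub = active.submatrix(C)
    if n_timescales > sub.shape[0] - 1:
        raise DimensionError(
            f"requested {n_timescales} timescales but only {sub.shape[0]} connected "
            f"states at lag {lag}"
        )
    model = estimate_reversible_msm(sub, lag=lag, dt=dt, active_set=active.states)
    return model.timescales(n_timescales)


def implied_timescales(
    dtrajs: list[np.ndarray],
    lags: list[int],
    n_timescales: int,
    dt: float = 1.0,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> ImpliedTimescales:
    """Timescales vs lag with optional trajectory-bootstrap intervals.

    A lag-independent (flat) profile within the bands supports Markovianity
    at those lags.  Bootstrap resamples whole trajectories with replacement,
    which respects the within-trajectory time correlation.
    """
    dtrajs = [np.asarray(d, int) for d in dtrajs]
    ts = np.array([_its_single(dtrajs, lag, n_timescales, dt) for lag in lags])
    lower = upper = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = np.full((n_bootstrap, len(lags), n_timescales), np.nan)
        for b in range(n_bootstrap):
            pick = rng.integers(0, len(dtrajs), len(dtrajs))
            sample = [dtrajs[i] for i in pick]
            for li, lag in enumerate(lags):
                try:
                    boots[b, li] = _its_single(sample, lag, n_timescales, dt)
                except (DepsikinError, DimensionError):
                    pass
        lower = np.nanpercentile(boots, 2.5, axis=0)
        upper = np.nanpercentile(boots, 97.5, axis=0)
    return ImpliedTimescales(np.asarray(lags), ts, lower, upper, n_bootstrap)


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov test

@dataclass
class CKTestResult:
    """Predicted vs re-estimated state self-transition probabilities.

    ``predicted[k-1, s]`` is ``(T(tau)^k)_{ss}``; ``estimated[k-1, s]`` the
    same entry of a model re-estimated at lag ``k*tau``.  Bootstrap bands
    (if requested) bracket the re-estimated values.
    """

    steps: np.ndarray
    states: tuple[int, ...]
    predicted: np.ndarray
    estimated: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def within_bands(self) -> np.ndarray:
        if self.lower is None or self.upper is None:
            raise DepsikinError("no bootstrap bands were computed")
        with np.errstate(invalid="ignore"):
            return (self.predicted >= self.lower) & (self.predicted <= self.upper)


def _ck_estimated_diag(dtrajs, lag, states):
    """Diagonal of a reversible model re-estimated at the given lag, mapped
    onto the reference state set (nan where a state drops out)."""
    C = count_transitions(dtrajs, lag, n_states=max(states) + 1)
    sub = C[np.ix_(states, states)]
    active = largest_connected_set(sub)
    diag = np.full(len(states), np.nan)
    if len(active.states) >= 1 and active.submatrix(sub).sum() > 0:
        try:
            model = estimate_reversible_msm(active.submatrix(sub), lag=lag)
        except DepsikinError:
            return diag
        for local, s in enumerate(active.states):
            diag[s] = model.transition_matrix[local, local]
    return diag


def ck_test(
    msm: MarkovModel,
    dtrajs: list[np.ndarray],
    n_steps: int,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> CKTestResult:
    """Chapman-Kolmogorov validation: compare T(tau)^k with T(k*tau).

    Agreement (within the bootstrap bands) for k up to ``n_steps`` supports
    the Markov assumption at lag tau.  k = 1 is exact by construction and
    serves as a sanity anchor.
    """
    if n_steps < 1:
        raise DimensionError("n_steps must be >= 1")
    dtrajs = [np.asarray(d, int) for d in dtrajs]
    states = msm.active_set
    steps = np.arange(1, n_steps + 1)
    predicted = np.empty((n_steps, len(states)))
    estimated = np.empty((n_steps, len(states)))
    for k in steps:
        Tk = np.linalg.matrix_power(msm.transition_matrix, k)
        predicted[k - 1] = np.diag(Tk)
        estimated[k - 1] = _ck_estimated_diag(dtrajs, k * msm.lag, states)

    lower = upper = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = np.full((n_bootstrap, n_steps, len(states)), np.nan)
        for b in range(n_bootstrap):
            pick = rng.integers(0, len(dtrajs), len(dtrajs))
            sample = [dtrajs[i] for i in pick]
            for k in steps:
                boots[b, k - 1] = _ck_estimated_diag(sample, k * msm.lag, states)
        lower = np.nanpercentile(boots, 2.5, axis=0)
        upper = np.nanpercentile(boots, 97.5, axis=0)
    return CKTestResult(steps, states, predicted, estimated, lower, upper)


# ---------------------------------------------------------------------------
# symmetry diagnostic

@dataclass(frozen=True)
class SymmetryPairDiagnostic:
    """Population comparison for one pair of C2-equivalent states."""

    state_i: int
    state_j: int
    pi_i: float
    pi_j: float

    @property
    def abs_difference(self) -> float:
        return abs(self.pi_i - self.pi_j)

    @property
    def ratio(self) -> float:
        lo, hi = sorted((self.pi_i, self.pi_j))
        return hi / lo if lo > 0 else float("inf")


def symmetry_diagnostic(
    msm: MarkovModel, pairing: list[tuple[int, int]]
) -> list[SymmetryPairDiagnostic]:
    """Convergence check from molecular symmetry.

    States that are chemically identical up to a C2 rotation must carry
    equal equilibrium populations; the per-pair absolute difference and
    ratio quantify how far the sampling is from that limit (both shrink to
    zero/one as trajectories lengthen).
    """
    pi = msm.stationary_distribution
    out = []
    for i, j in pairing:
        local = {s: k for k, s in enumerate(msm.active_set)}
        if i not in local or j not in local:
            raise DimensionError(f"pair ({i}, {j}) not contained in the active set")
        out.append(SymmetryPairDiagnostic(i, j, float(pi[local[i]]), float(pi[local[j]])))
    return out
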