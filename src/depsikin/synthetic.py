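"""Seeded synthetic-data generators for every pipeline stage.

Each generator draws from the forward model of the corresponding analysis
stage so that the whole pipeline can be exercised and validated without any
experimental spectra or MD trajectories:

* ``gen_exsy``      -- magnetization transfer M = expm(L tm) diag(M0) with
                       multiplicative volume noise (the published analysis
                       assumes roughly 20% volume errors);
* ``gen_titration`` -- speciation-derived titration curves on the
                       experimental salt schedule with additive shift noise
                       and lognormal ratio noise;
* ``gen_markov``    -- a discrete-state Markov chain emitted through
                       per-state Gaussians, linearly mixed into
                       dihedral-like angle features;
* ``gen_decay``     -- mono-exponential CPMG decays on the printed delay
                       grid with additive intensity noise.

One integer seed per spec is split deterministically into per-stream
substreams (``numpy`` SeedSequence), so regenerating any one stage is
stable.  Identical specs produce bit-identical output, and every generator
returns its ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import binding, exsy, relaxation
from .errors import DimensionError

__all__ = [
    "ExsySpec",
    "TitrationSpec",
    "MarkovSpec",
    "DecaySpec",
    "gen_exsy",
    "gen_titration",
    "gen_markov",
    "gen_decay",
]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


# ---------------------------------------------------------------------------
# EXSY

@dataclass(frozen=True)
class ExsySpec:
    """Ground truth for a three-site (or custom) exchange experiment.

    ``k_sym_to_asym`` / ``k_asym_to_sym`` are the per-pathway site-to-site
    rates (s^-1); defaults are the PF1022A-like values.  ``r1`` is the
    common auto-relaxation rate; ``noise`` the multiplicative volume error
    (0.2 = the assumed 20%).
    """

    seed: int
    k_sym_to_asym: float = 0.16
    k_asym_to_sym: float = 0.09
    r1: float = 2.0
    mixing_time: float = 0.1
    magnetic_fractions: tuple[float, ...] = (1.0, 1.5, 1.5)
    noise: float = 0.2
    network: exsy.ExchangeNetwork | None = None


@dataclass
class ExsyData:
    volumes: exsy.ExsyVolumeSet
    network: exsy.ExchangeNetwork
    true_L: np.ndarray
    true_k1: float
    true_k2: float


def exsy_rate_matrix(k12: float, k21: float, r1: float) -> np.ndarray:
    """Rate matrix for the canonical sym (A) <-> asym (B, C) network.

    Column j holds the rates out of site j; ``L[i, j]`` is the rate j -> i,
    B <-> C exchange is forbidden.
    """
    return np.array(
        [
            [-2 * k12 - r1, k21, k21],
            [k12, -k21 - r1, 0.0],
            [k12, 0.0, -k21 - r1],
        ]
    )


def gen_exsy(spec: ExsySpec) -> ExsyData:
    """Noisy EXSY volume matrix from the exact magnetization-transfer model."""
    rng = _rng(spec.seed, 0)
    network = spec.network or exsy.two_conformer_network(
        magnetic_fractions={
            s: f for s, f in zip(("A", "B", "C"), spec.magnetic_fractions)
        }
    )
    L = exsy_rate_matrix(spec.k_sym_to_asym, spec.k_asym_to_sym, spec.r1)
    m0 = network.fractions_vector()
    clean = exsy.forward_exsy(L, m0, spec.mixing_time)
    factors = (
        rng.uniform(1 - spec.noise, 1 + spec.noise, clean.shape)
        if spec.noise > 0
        else np.ones_like(clean)
    )
    volumes = exsy.ExsyVolumeSet(spec.mixing_time, clean * factors)
    return ExsyData(volumes, network, L, spec.k_sym_to_asym, spec.k_asym_to_sym)


# ---------------------------------------------------------------------------
# titration

@dataclass(frozen=True)
class TitrationSpec:
    """Titration study design: 5 mM peptide, salt 0-200 mM by default.

    ``sigma_shift`` is the additive shift noise (ppm, default 0.002 -- the
    order of digital resolution in a 1D 1H spectrum); ``sigma_log_ratio``
    the lognormal error of the integration-derived conformer ratio.
    """

    seed: int
    model: binding.EquilibriumModel = field(
        default_factory=lambda: binding.EquilibriumModel(
            Kc=1.0 / 7.0, K1=150.0, K2=80.0, delta_S=4.45, delta_SM=4.35, delta_S2M=4.55
        )
    )
    P_total: float = binding.DEFAULT_PEPTIDE_M
    salt_grid: tuple[float, ...] = binding.DEFAULT_SALT_GRID_M
    sigma_shift: float = 0.002
    sigma_log_ratio: float = 0.0


@dataclass
class TitrationData:
    points: list[binding.TitrationPoint]
    model: binding.EquilibriumModel


def gen_titration(spec: TitrationSpec) -> TitrationData:
    rng = _rng(spec.seed, 1)
    clean = binding.simulate_titration(spec.model, spec.P_total, spec.salt_grid)
    noisy = []
    for pt in clean:
        delta = pt.delta_obs + (rng.normal(0.0, spec.sigma_shift) if spec.sigma_shift > 0 else 0.0)
        ratio = pt.ratio_obs * (
            np.exp(rng.normal(0.0, spec.sigma_log_ratio)) if spec.sigma_log_ratio > 0 else 1.0
        )
        noisy.append(
            binding.TitrationPoint(pt.P_total, pt.M_total, delta_obs=delta, ratio_obs=ratio)
        )
    return TitrationData(noisy, spec.model)


# ---------------------------------------------------------------------------
# Markov / dihedral trajectories

@dataclass(frozen=True)
class MarkovSpec:
    """Discrete chain -> Gaussian emissions -> mixed dihedral-like features.

    ``transition_matrix`` is the ground-truth row-stochastic matrix at one
    frame; emissions are isotropic Gaussians around per-state means in a
    latent space that is linearly mixed into ``n_features`` angle-like
    coordinates (wrapped to (-180, 180] degrees).
    """

    seed: int
    transition_matrix: tuple[tuple[float, ...], ...] = (
        (0.99, 0.01),
        (0.01, 0.99),
    )
    emission_means: tuple[tuple[float, ...], ...] | None = None
    emission_sigma: float = 10.0
    n_features: int = 4
    n_frames: int = 100_000
    n_trajs: int = 1
    dt: float = 1.0


@dataclass
class MarkovData:
    trajs: list["np.ndarray"]
    features: list
    dtrajs: list[np.ndarray]
    transition_matrix: np.ndarray
    spec: MarkovSpec


def _sample_chain(T: np.ndarray, n: int, rng: np.random.Generator, start: int) -> np.ndarray:
    cum = np.cumsum(T, axis=1)
    out = np.empty(n, dtype=int)
    s = start
    u = rng.random(n)
    for t in range(n):
        out[t] = s
        s = int(np.searchsorted(cum[s], u[t]))
    return out


def gen_markov(spec: MarkovSpec):
    """Feature trajectories with known discrete dynamics.

    Returns ``MarkovData`` whose ``features`` are ``FeatureTrajectory``
    objects (angle features, degrees) and whose ``dtrajs`` are the true
    state sequences.
    """
    from .msm import FeatureTrajectory

    T = np.asarray(spec.transition_matrix, float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise DimensionError("transition matrix must be square")
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
        raise DimensionError("transition matrix rows must sum to 1")
    m = T.shape[0]
    rng = _rng(spec.seed, 2)

    if spec.emission_means is None:
        # spread the states on a ring in a 2D latent space, well separated
        ang = 2 * np.pi * np.arange(m) / m
        means = 90.0 * np.column_stack([np.cos(ang), np.sin(ang)])
    else:
        means = np.asarray(spec.emission_means, float)
    latent_dim = means.shape[1]
    mix = rng.standard_normal((latent_dim, spec.n_features))
    mix /= np.linalg.norm(mix, axis=0, keepdims=True)

    # stationary start state distribution
    evals, evecs = np.linalg.eig(T.T)
    pi = np.real(evecs[:, np.argmax(np.real(evals))])
    pi = np.abs(pi) / np.abs(pi).sum()

    trajs, feats, dtrajs = [], [], []
    for k in range(spec.n_trajs):
        start = int(rng.choice(m, p=pi))
        d = _sample_chain(T, spec.n_frames, rng, start)
        latent = means[d] + spec.emission_sigma * rng.standard_normal((spec.n_frames, latent_dim))
        angles = latent @ mix
        angles = (angles + 180.0) % 360.0 - 180.0
        # map the wrap boundary -180 -> 180 to keep angles in (-180, 180]
        angles[angles == -180.0] = 180.0
        trajs.append(angles)
        feats.append(FeatureTrajectory(_embed(angles), spec.dt, f"synthetic-{k}"))
        dtrajs.append(d)
    return MarkovData(trajs, feats, dtrajs, T, spec)


def _embed(angles_deg: np.ndarray) -> np.ndarray:
    rad = np.deg2rad(angles_deg)
    out = np.empty((angles_deg.shape[0], 2 * angles_deg.shape[1]))
    out[:, 0::2] = np.sin(rad)
    out[:, 1::2] = np.cos(rad)
    return out


# ---------------------------------------------------------------------------
# decay

@dataclass(frozen=True)
class DecaySpec:
    """Mono-exponential decay on the standard ten-delay CPMG grid."""

    seed: int
    I0: float = 100.0
    T2: float = 0.1
    delays: tuple[float, ...] = relaxation.CPMG_DELAY_GRID_S
    noise: float = 0.05  # additive, relative to I0
    site: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.T2 > 0:
            raise DimensionError(f"T2 must be > 0, got {self.T2}")


@dataclass
class DecayData:
    curve: relaxation.DecayCurve
    I0: float
    T2: float


def gen_decay(spec: DecaySpec) -> DecayData:
    rng = _rng(spec.seed, 3)
    t = np.asarray(spec.delays, float)
    clean = spec.I0 * np.exp(-t / spec.T2)
    noise = spec.noise * spec.I0 * rng.standard_normal(t.shape) if spec.noise > 0 else 0.0
    curve = relaxation.DecayCurve(t, clean + noise, site=spec.site)
    return DecayData(curve, spec.I0, spec.T2)
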