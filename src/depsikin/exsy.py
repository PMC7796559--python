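"""Exchange-rate extraction from EXSY peak volumes by matrix logarithm.

Slow conformational exchange between the symmetric (all-*trans*) and the
asymmetric (one *cis*-amide) macrocycle conformers of cyclic
octadepsipeptides produces exchange (EXSY) cross-peaks in ROESY/NOESY-type
spectra.  For magnetization vector ``M`` the mixing-time evolution is

    M(tm) = expm(L * tm) @ M(0)

where ``L = K - R`` collects the site-to-site rate constants ``K`` and the
auto-relaxation rates ``R``.  Normalizing the measured volume matrix by the
per-site "magnetic fractions" (relative 1H intensities, approximating
``M(0)``) gives the transfer matrix ``A``, and the rate matrix follows from
its principal matrix logarithm::

    L = ln(A) / tm

Off-diagonal entry ``L[i, j]`` is the magnetization-transfer rate from site
``j`` into site ``i``; the diagonal carries minus the outgoing rates minus
the auto-relaxation rate of the site.  Because volumes and magnetic
fractions are usually recorded in different arbitrary units, a common scale
factor is absorbed into the diagonal (and hence the apparent relaxation
rates); the off-diagonal exchange rates are unaffected.

For a C2-symmetric macrocycle two degenerate transfer pathways connect the
symmetric site with the two asymmetric sites, so the *mechanistic*
conformational rate out of the symmetric state is twice the averaged
site-to-site rate of that pathway set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import DimensionError, MatrixLogError

__all__ = [
    "ExchangeNetwork",
    "ExsyVolumeSet",
    "KineticResult",
    "RateUncertainty",
    "build_transfer_matrix",
    "rate_matrix_from_exsy",
    "extract_site_rates",
    "forward_exsy",
    "rate_uncertainty",
    "two_conformer_network",
]

#: averaged rates more negative than this (s^-1) fail validation outright;
#: small negatives are reported as-is with a warning (volumes carry ~20% error)
NEGATIVE_RATE_FLOOR = -0.005


@dataclass(frozen=True)
class ExchangeNetwork:
    """Topology and normalization data of an exchange network.

    Parameters
    ----------
    site_labels
        Ordered site names; fixes the row/column order of every matrix.
    conformer_of_site
        Map site -> ``"symmetric"`` or ``"asymmetric"``.
    symmetry_pairs
        Groups of directed pathways ``(src, dst)`` that are chemically
        equivalent and whose rates are averaged together.  For the
        C2-symmetric three-site network this is
        ``[[("A","B"), ("A","C")], [("B","A"), ("C","A")]]``.
        Empty for molecules without C2 symmetry, in which case every allowed
        directed pathway forms its own singleton group.
    forbidden_pairs
        Unordered site pairs with no direct exchange (their recovered rates
        are reported as a diagnostic and should be ~0).
    magnetic_fractions
        Per-site relative 1H intensities (> 0), arbitrary common unit.
    c2_symmetric
        Whether the symmetric conformer has a C2 axis making two transfer
        pathways degenerate (true for PF1022A/emodepside-like molecules).
    k1_group
        Index of the pathway group reported as ``k1``.  ``None`` (default)
        names the group with the larger averaged rate ``k1``, matching the
        published rate tables.
    """

    site_labels: tuple[str, ...]
    conformer_of_site: dict[str, str]
    symmetry_pairs: tuple[tuple[tuple[str, str], ...], ...] = ()
    forbidden_pairs: tuple[tuple[str, str], ...] = ()
    magnetic_fractions: dict[str, float] = field(default_factory=dict)
    c2_symmetric: bool = True
    k1_group: int | None = None

    def __post_init__(self) -> None:
        if len(self.site_labels) < 2:
            raise DimensionError("an exchange network needs at least 2 sites")
        if len(set(self.site_labels)) != len(self.site_labels):
            raise DimensionError("duplicate site labels")
        for s in self.site_labels:
            frac = self.magnetic_fractions.get(s)
            if frac is None or not frac > 0:
                raise DimensionError(
                    f"magnetic fraction of site {s!r} must be a positive number, got {frac!r}"
                )
            if self.conformer_of_site.get(s) not in ("symmetric", "asymmetric"):
                raise DimensionError(
                    f"site {s!r} must be declared 'symmetric' or 'asymmetric'"
                )
        for group in self.symmetry_pairs:
            for src, dst in group:
                if src not in self.site_labels or dst not in self.site_labels:
                    raise DimensionError(f"symmetry pathway ({src}, {dst}) references unknown site")
        if not self.c2_symmetric and self.symmetry_pairs:
            raise DimensionError("symmetry_pairs must be empty when c2_symmetric is false")

    @property
    def n_sites(self) -> int:
        return len(self.site_labels)

    def index(self, site: str) -> int:
        return self.site_labels.index(site)

    def fractions_vector(self) -> np.ndarray:
        return np.array([self.magnetic_fractions[s] for s in self.site_labels], float)

    def is_forbidden(self, a: str, b: str) -> bool:
        return (a, b) in self.forbidden_pairs or (b, a) in self.forbidden_pairs

    def pathway_groups(self) -> list[list[tuple[str, str]]]:
        """Directed pathway groups whose rates are averaged together."""
        if self.symmetry_pairs:
            return [list(g) for g in self.symmetry_pairs]
        groups = []
        for src in self.site_labels:
            for dst in self.site_labels:
                if src != dst and not self.is_forbidden(src, dst):
                    groups.append([(src, dst)])
        return groups


def two_conformer_network(
    symmetric_site: str = "A",
    asymmetric_sites: tuple[str, str] = ("B", "C"),
    magnetic_fractions: dict[str, float] | None = None,
    c2_symmetric: bool = True,
) -> ExchangeNetwork:
    """Canonical three-site network: one symmetric site exchanging with two
    asymmetric sites over degenerate pathways, no direct exchange between
    the asymmetric sites."""
    a, (b, c) = symmetric_site, asymmetric_sites
    fracs = magnetic_fractions or {a: 1.0, b: 1.0, c: 1.0}
    return ExchangeNetwork(
        site_labels=(a, b, c),
        conformer_of_site={a: "symmetric", b: "asymmetric", c: "asymmetric"},
        symmetry_pairs=(((a, b), (a, c)), ((b, a), (c, a))) if c2_symmetric else (),
        forbidden_pairs=((b, c),),
        magnetic_fractions=fracs,
        c2_symmetric=c2_symmetric,
    )


@dataclass(frozen=True)
class ExsyVolumeSet:
    """Square matrix of EXSY cross- and diagonal-peak volumes at one mixing time.

    ``volumes[i, j]`` is the volume of the peak at (F1 = site i, F2 = site j);
    row/column order follows ``ExchangeNetwork.site_labels``.
    """

    mixing_time: float
    volumes: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, float)
        object.__setattr__(self, "volumes", v)
        if not self.mixing_time > 0:
            raise DimensionError(f"mixing time must be > 0, got {self.mixing_time}")
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DimensionError(f"volume matrix must be square, got shape {v.shape}")
        if np.any(np.diag(v) <= 0):
            raise DimensionError("diagonal peak volumes must be > 0")


@dataclass
class KineticResult:
    """Exchange rates extracted from one EXSY volume matrix.

    ``site_rates`` maps each directed pathway ``"X->Y"`` to its raw
    off-diagonal rate.  ``k1``/``k2`` are arithmetic means over the two
    symmetry-equivalent pathway sets (``k1`` the larger by default), and the
    mechanistic rates correct for pathway degeneracy: with a C2 axis,
    ``k1_mech = 2 * k1`` (two equivalent pathways realise the same
    conformational transition), otherwise ``k1_mech = k1``.  ``K_eq`` is
    defined as ``k1_mech / k2_mech`` -- the ratio of the two mechanistic
    rates as named here; no thermodynamic direction is implied.
    """

    transfer_matrix_A: np.ndarray
    rate_matrix: np.ndarray
    site_rates: dict[str, float]
    k1: float
    k2: float
    kex: float
    k1_mech: float
    k2_mech: float
    K_eq: float
    auto_relaxation: dict[str, float]
    forbidden_rates: dict[str, float]
    group_rates: tuple[tuple[float, ...], ...]
    warnings: list[str] = field(default_factory=list)

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Rates rounded for reporting (two decimals, as in published tables)."""
        return {
            "k1": round(self.k1, ndigits),
            "k2": round(self.k2, ndigits),
            "kex": round(self.kex, ndigits),
            "k1_mech": round(self.k1_mech, ndigits),
            "k2_mech": round(self.k2_mech, ndigits),
        }


def build_transfer_matrix(volumes: ExsyVolumeSet, network: ExchangeNetwork) -> np.ndarray:
    """Normalize the volume matrix column-wise by the magnetic fractions.

    Returns ``A = M @ diag(M0)^-1``, i.e. ``A[i, j] = I[i, j] / M0[j]``.
    """
    v = volumes.volumes
    if v.shape[0] != network.n_sites:
        raise DimensionError(
            f"volume matrix is {v.shape[0]}x{v.shape[1]} but network has {network.n_sites} sites"
        )
    m0 = network.fractions_vector()
    return v / m0[None, :]


def rate_matrix_from_exsy(
    A: np.ndarray,
    tm: float,
    imag_tol: float = 1e-8,
    cond_threshold: float = 1e8,
) -> np.ndarray:
    """Principal matrix logarithm of the transfer matrix, divided by tm.

    The log is taken through the eigendecomposition of ``A``; if the
    eigenvector matrix is ill-conditioned (condition number above
    ``cond_threshold``) a Schur-based real matrix logarithm is used instead.

    Raises
    ------
    MatrixLogError
        If any eigenvalue is non-positive or its imaginary part exceeds
        ``imag_tol`` relative to the spectral radius.  Complex or negative
        eigenvalues signal volumes that are inconsistent with first-order
        exchange (usually noise), so they are a hard error rather than being
        silently realified.
    """
    A = np.asarray(A, float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DimensionError(f"transfer matrix must be square, got shape {A.shape}")
    if not tm > 0:
        raise DimensionError(f"mixing time must be > 0, got {tm}")

    evals, evecs = np.linalg.eig(A)
    scale = np.max(np.abs(evals))
    for lam in evals:
        if abs(lam.imag) > imag_tol * scale:
            raise MatrixLogError(
                f"eigenvalue {lam:.6g} of the transfer matrix has a non-negligible "
                "imaginary part; the peak volumes are likely too noisy for a "
                "consistent first-order exchange model"
            )
        if lam.real <= 0:
            raise MatrixLogError(
                f"eigenvalue {lam.real:.6g} of the transfer matrix is not positive; "
                "the principal matrix logarithm is undefined (check volumes for noise)"
            )
    if np.linalg.cond(evecs) < cond_threshold:
        logA = evecs @ np.diag(np.log(evals.real)) @ np.linalg.inv(evecs)
    else:
        # eigenvectors nearly parallel: Schur-based real logarithm is stabler
        logA = scipy.linalg.logm(A)
    resid = np.max(np.abs(logA.imag)) if np.iscomplexobj(logA) else 0.0
    if resid > imag_tol * max(1.0, np.max(np.abs(logA.real))):
        raise MatrixLogError(
            f"matrix logarithm has imaginary residue {resid:.3g}; "
            "volumes are inconsistent with first-order exchange"
        )
    return np.real(logA) / tm


def extract_site_rates(L: np.ndarray, network: ExchangeNetwork) -> KineticResult:
    """Read pathway rates off the rate matrix and average symmetry-equivalent ones.

    ``L[i, j]`` (i != j) is the rate from site ``j`` into site ``i``.
    Averaged rates of the two pathway groups become ``k1`` (larger, unless
    ``network.k1_group`` says otherwise) and ``k2``; ``kex = k1 + k2``.
    Rates of forbidden pairs are excluded from the averages and reported as
    a diagnostic (they should be ~0 when the declared topology is right).
    """
    L = np.asarray(L, float)
    n = network.n_sites
    if L.shape != (n, n):
        raise DimensionError(f"rate matrix is {L.shape} but network has {n} sites")

    site_rates: dict[str, float] = {}
    for src in network.site_labels:
        for dst in network.site_labels:
            if src == dst or network.is_forbidden(src, dst):
                continue
            site_rates[f"{src}->{dst}"] = float(L[network.index(dst), network.index(src)])

    forbidden = {}
    for a, b in network.forbidden_pairs:
        forbidden[f"{a}->{b}"] = float(L[network.index(b), network.index(a)])
        forbidden[f"{b}->{a}"] = float(L[network.index(a), network.index(b)])

    groups = network.pathway_groups()
    group_vals = tuple(
        tuple(site_rates[f"{src}->{dst}"] for src, dst in g) for g in groups
    )
    group_means = [float(np.mean(v)) for v in group_vals]

    msgs: list[str] = []
    for g, mean in zip(groups, group_means):
        if mean < NEGATIVE_RATE_FLOOR:
            raise MatrixLogError(
                f"averaged rate {mean:.4g} s^-1 for pathway group {g} is negative "
                "beyond tolerance; volumes fail validation"
            )
        if mean < 0:
            msgs.append(
                f"averaged rate {mean:.4g} s^-1 for pathway group {g} is slightly "
                "negative (consistent with ~20% volume errors); reported as-is"
            )

    if len(group_means) >= 2:
        if network.k1_group is not None:
            i1 = network.k1_group
            others = [i for i in range(len(group_means)) if i != i1]
            i2 = others[int(np.argmax([group_means[i] for i in others]))]
        else:
            order = np.argsort(group_means)[::-1]
            i1, i2 = int(order[0]), int(order[1])
        k1, k2 = group_means[i1], group_means[i2]
    else:
        k1, k2 = group_means[0], 0.0

    kex = k1 + k2
    if network.c2_symmetric:
        k1_mech, k2_mech = 2.0 * k1, k2
    else:
        k1_mech, k2_mech = k1, k2
    K_eq = k1_mech / k2_mech if k2_mech != 0 else float("inf")

    # Eq-structure diagonal: -(outgoing rates) - R1, so R1 = -(column sum).
    # A global volume/M0 unit mismatch shifts all diagonals equally, so these
    # are estimates up to a common additive constant.
    auto_relax = {
        s: float(-np.sum(L[:, network.index(s)])) for s in network.site_labels
    }

    for msg in msgs:
        warnings.warn(msg, stacklevel=2)
    return KineticResult(
        transfer_matrix_A=np.array([]),  # filled by extract_from_volumes
        rate_matrix=L,
        site_rates=site_rates,
        k1=k1,
        k2=k2,
        kex=kex,
        k1_mech=k1_mech,
        k2_mech=k2_mech,
        K_eq=K_eq,
        auto_relaxation=auto_relax,
        forbidden_rates=forbidden,
        group_rates=group_vals,
        warnings=msgs,
    )


def extract_from_volumes(
    volumes: ExsyVolumeSet,
    network: ExchangeNetwork,
    imag_tol: float = 1e-8,
) -> KineticResult:
    """Full chain: volumes -> transfer matrix -> matrix log -> averaged rates."""
    A = build_transfer_matrix(volumes, network)
    L = rate_matrix_from_exsy(A, volumes.mixing_time, imag_tol=imag_tol)
    result = extract_site_rates(L, network)
    result.transfer_matrix_A = A
    return result


def forward_exsy(L: np.ndarray, M0: np.ndarray, tm: float) -> np.ndarray:
    """Forward model: volume matrix ``M = expm(L * tm) @ diag(M0)``.

    Exact inverse of the extraction chain in the noise-free case.
    """
    L = np.asarray(L, float)
    M0 = np.asarray(M0, float)
    if not tm > 0:
        raise DimensionError(f"mixing time must be > 0, got {tm}")
    if L.ndim != 2 or L.shape[0] != L.shape[1] or M0.shape != (L.shape[0],):
        raise DimensionError(f"inconsistent shapes L={L.shape}, M0={M0.shape}")
    return scipy.linalg.expm(L * tm) @ np.diag(M0)


@dataclass
class RateUncertainty:
    """Monte-Carlo spread of the extracted rates under volume noise."""

    point: KineticResult
    medians: dict[str, float]
    interval68: dict[str, tuple[float, float]]
    interval95: dict[str, tuple[float, float]]
    n_rep: int
    n_failed: int
    noise_fraction: float


def rate_uncertainty(
    volumes: ExsyVolumeSet,
    network: ExchangeNetwork,
    noise_fraction: float,
    n_rep: int,
    seed: int,
    distribution: str = "uniform",
) -> RateUncertainty:
    """Propagate multiplicative volume noise through the extraction chain.

    Each replicate multiplies every volume by an independent factor drawn
    either uniformly from ``[1 - f, 1 + f]`` (default) or lognormally with
    ``sigma = f``; replicates whose matrix logarithm fails are counted and
    excluded.  Reported are the median and the central 68%/95% intervals of
    k1, k2 and kex.
    """
    if noise_fraction < 0:
        raise DimensionError("noise_fraction must be >= 0")
    if n_rep < 2:
        raise DimensionError("n_rep must be >= 2")
    rng = np.random.default_rng(seed)
    point = extract_from_volumes(volumes, network)

    samples: dict[str, list[float]] = {"k1": [], "k2": [], "kex": []}
    n_failed = 0
    for _ in range(n_rep):
        if distribution == "uniform":
            factors = rng.uniform(1 - noise_fraction, 1 + noise_fraction, volumes.volumes.shape)
        elif distribution == "lognormal":
            factors = rng.lognormal(0.0, noise_fraction, volumes.volumes.shape) if noise_fraction > 0 else np.ones(volumes.volumes.shape)
        else:
            raise DimensionError(f"unknown noise distribution {distribution!r}")
        noisy = ExsyVolumeSet(volumes.mixing_time, volumes.volumes * factors)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = extract_from_volumes(noisy, network)
        except MatrixLogError:
            n_failed += 1
            continue
        samples["k1"].append(res.k1)
        samples["k2"].append(res.k2)
        samples["kex"].append(res.kex)

    if not samples["k1"]:
        raise MatrixLogError(
            f"all {n_rep} noise replicates failed the matrix logarithm; "
            "the volume matrix is inconsistent with first-order exchange"
        )
    med, i68, i95 = {}, {}, {}
    for key, vals in samples.items():
        arr = np.asarray(vals)
        med[key] = float(np.median(arr))
        i68[key] = (float(np.percentile(arr, 16)), float(np.percentile(arr, 84)))
        i95[key] = (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5)))
    return RateUncertainty(point, med, i68, i95, n_rep, n_failed, noise_fraction)
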