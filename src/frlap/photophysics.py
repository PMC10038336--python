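"""Spectral lineshapes and Förster transfer rates for PCB chromophores.

FRL-AP shows a very broad absorbance band centred at 621 nm (β-PCB) and a
very sharp, more intense band at 709 nm (α-PCB) with fluorescence at
714 nm.  Lineshapes here are sums of Gaussians in wavenumber space (a main
band plus an optional vibronic shoulder) evaluated on a common nm grid;
emission is the mirror image of the main absorption band displaced by the
Stokes shift and area-normalised.

Pair transfer rates follow point-dipole Förster theory:

    κ²  = (μ̂_D·μ̂_A − 3 (μ̂_D·r̂)(μ̂_A·r̂))²
    J   = ∫ F_D(λ) ε_A(λ) λ⁴ dλ           [M⁻¹ cm⁻¹ nm⁴, F_D area-normalised]
    R0⁶ = 8.79×10⁻⁵ · κ² n⁻⁴ Φ_D · J      [R0 in Å]
    k   = (1/τ_D) (R0/R)⁶                  [ps⁻¹]

The overlap integral is direction specific (β→α uses β emission × α
absorption and vice versa), so forward and backward rates differ and
transfer is strongly biased toward the red α-PCB.  Because the absolute
transition-dipole strengths of the PCBs in situ are not independently
fixed, the rate network carries a dimensionless global ``prefactor`` that
is calibrated against the measured 517-fs β→α transfer time (see
``frlap.calibration``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralModel",
    "LineshapeParams",
    "MediumParams",
    "RateMatrix",
    "make_lineshape",
    "default_spectra",
    "kappa_squared",
    "overlap_integral",
    "forster_radius",
    "pair_rate",
    "build_rate_matrix",
    "FORSTER_PREFACTOR",
    "DEFAULT_GRID",
]

#: R0⁶ = FORSTER_PREFACTOR · κ² n⁻⁴ Φ_D J  with J in M⁻¹cm⁻¹nm⁴ and R0 in Å.
#: 8.79e-5 = 9 ln10 / (128 π⁵ N_A') with N_A' = N_A·10⁻²³ — the standard
#: constant of the Å/nm/M⁻¹cm⁻¹ unit chain.
FORSTER_PREFACTOR = 8.79e-5

#: shared wavelength grid: 500–800 nm, 0.5 nm step
DEFAULT_GRID = np.arange(500.0, 800.0 + 1e-9, 0.5)


@dataclass(frozen=True)
class LineshapeParams:
    """Gaussian-in-wavenumber band model for one PCB class.

    ``abs_width_wn`` is the Gaussian σ of the main band in cm⁻¹; the
    vibronic shoulder sits ``vib_offset_wn`` above the main band with
    relative amplitude ``vib_amp`` and width ``vib_width_wn``.
    """

    abs_peak_nm: float
    em_peak_nm: float
    abs_width_wn: float
    peak_extinction: float
    vib_offset_wn: float = 0.0
    vib_amp: float = 0.0
    vib_width_wn: float = 700.0
    tail_offset_wn: float = 0.0  # red (low-energy) tail below the main band
    tail_amp: float = 0.0
    tail_width_wn: float = 700.0


#: Defaults for the two PCB classes.  α: sharp 709/714 nm pair with a weak
#: broad vibronic wing (which also carries the small direct α excitation at
#: 580 nm).  β: broad 621 nm band; its emission is not resolved in the
#: intact complex (transfer outruns fluorescence), so the β emission
#: position acts as a calibration parameter of the transfer network — the
#: default 665 nm, together with the dipole-orientation convention, anchors
#: the relative α→α and terminal-PCB transfer rates to the measured slow
#: kinetics (see frlap.calibration and docs/methods.md).
DEFAULT_LINESHAPES = {
    "alpha": LineshapeParams(abs_peak_nm=709.0, em_peak_nm=714.0,
                             abs_width_wn=170.0, peak_extinction=2.5e5,
                             vib_offset_wn=1900.0, vib_amp=0.14,
                             vib_width_wn=550.0),
    "beta": LineshapeParams(abs_peak_nm=621.0, em_peak_nm=665.0,
                            abs_width_wn=550.0, peak_extinction=1.2e5,
                            vib_offset_wn=1200.0, vib_amp=0.25,
                            vib_width_wn=700.0),
}


@dataclass
class SpectralModel:
    site_class: str
    grid: np.ndarray  # wavelength, nm
    absorption: np.ndarray  # M⁻¹ cm⁻¹
    emission: np.ndarray  # area-normalised over the grid (nm⁻¹)
    peak_abs: float
    peak_em: float


@dataclass(frozen=True)
class MediumParams:
    refractive_index: float = 1.33
    donor_quantum_yield: float = 0.5
    donor_lifetime_ps: float = 1500.0

    def __post_init__(self) -> None:
        if self.refractive_index < 1:
            raise ValueError("refractive index must be >= 1")
        if not 0 < self.donor_quantum_yield <= 1:
            raise ValueError("quantum yield must be in (0, 1]")
        if self.donor_lifetime_ps <= 0:
            raise ValueError("donor lifetime must be > 0")


def _gaussian_wn(grid_nm: np.ndarray, peak_nm: float, sigma_wn: float,
                 amplitude: float = 1.0) -> np.ndarray:
    nu = 1e7 / grid_nm
    nu0 = 1e7 / peak_nm
    return amplitude * np.exp(-0.5 * ((nu - nu0) / sigma_wn) ** 2)


def make_lineshape(site_class: str,
                   params: LineshapeParams | None = None,
                   grid: np.ndarray = DEFAULT_GRID) -> SpectralModel:
    """Absorption and (area-normalised) emission curves for one PCB class."""
    if params is None:
        params = DEFAULT_LINESHAPES[site_class]
    if not (grid[0] <= params.abs_peak_nm <= grid[-1]
            and grid[0] <= params.em_peak_nm <= grid[-1]):
        raise ValueError("band peaks must lie inside the wavelength grid")
    if params.em_peak_nm < params.abs_peak_nm:
        raise ValueError("emission peak must be red of the absorption peak")
    def _composite(center_nm: float, g: np.ndarray) -> np.ndarray:
        curve = _gaussian_wn(g, center_nm, params.abs_width_wn)
        if params.vib_amp > 0:
            nu_vib = 1e7 / center_nm + params.vib_offset_wn
            curve = curve + _gaussian_wn(g, 1e7 / nu_vib,
                                         params.vib_width_wn,
                                         params.vib_amp)
        if params.tail_amp > 0:
            nu_tail = 1e7 / center_nm - params.tail_offset_wn
            curve = curve + _gaussian_wn(g, 1e7 / nu_tail,
                                         params.tail_width_wn,
                                         params.tail_amp)
        return curve

    # shoulders skew the composite maximum; nudge the main-band centre so
    # the summed band peaks at the nominal wavelength
    fine = np.arange(params.abs_peak_nm - 30.0,
                     params.abs_peak_nm + 30.0, 0.02)
    center = params.abs_peak_nm
    for _ in range(3):
        center += params.abs_peak_nm - fine[np.argmax(_composite(center,
                                                                 fine))]
    absorption = _composite(center, grid)
    absorption = params.peak_extinction * absorption / absorption.max()
    # emission: mirror of the main absorption band shifted by the Stokes shift
    emission = _gaussian_wn(grid, params.em_peak_nm, params.abs_width_wn)
    emission = emission / np.trapezoid(emission, grid)
    return SpectralModel(site_class=site_class, grid=grid,
                         absorption=absorption, emission=emission,
                         peak_abs=params.abs_peak_nm,
                         peak_em=params.em_peak_nm)


def default_spectra(grid: np.ndarray = DEFAULT_GRID) -> dict[str, SpectralModel]:
    return {c: make_lineshape(c, grid=grid) for c in ("alpha", "beta")}


def kappa_squared(mu_d: np.ndarray, mu_a: np.ndarray,
                  r: np.ndarray) -> float:
    """Orientation factor κ² ∈ [0, 4] for unit dipoles and separation r."""
    r = np.asarray(r, dtype=float)
    rn = np.linalg.norm(r)
    if rn == 0:
        raise ValueError("separation vector must be nonzero")
    rhat = r / rn
    mu_d = np.asarray(mu_d, dtype=float)
    mu_a = np.asarray(mu_a, dtype=float)
    kappa = mu_d @ mu_a - 3.0 * (mu_d @ rhat) * (mu_a @ rhat)
    return float(kappa ** 2)


def overlap_integral(donor: SpectralModel, acceptor: SpectralModel) -> float:
    """J = ∫ F_D(λ) ε_A(λ) λ⁴ dλ in M⁻¹ cm⁻¹ nm⁴.

    Spectra on different grids are linearly interpolated onto their
    overlapping range.
    """
    if donor.grid.shape == acceptor.grid.shape and np.allclose(
            donor.grid, acceptor.grid):
        grid, fd, ea = donor.grid, donor.emission, acceptor.absorption
    else:
        lo = max(donor.grid[0], acceptor.grid[0])
        hi = min(donor.grid[-1], acceptor.grid[-1])
        if lo >= hi:
            raise ValueError("donor and acceptor grids do not overlap")
        step = min(np.diff(donor.grid).min(), np.diff(acceptor.grid).min())
        grid = np.arange(lo, hi + 1e-9, step)
        fd = np.interp(grid, donor.grid, donor.emission)
        ea = np.interp(grid, acceptor.grid, acceptor.absorption)
    return float(np.trapezoid(fd * ea * grid ** 4, grid))


def forster_radius(J: float, kappa2: float, medium: MediumParams) -> float:
    """Förster radius R0 (Å) from the overlap integral (M⁻¹cm⁻¹nm⁴)."""
    if J < 0:
        raise ValueError("overlap integral must be >= 0")
    r6 = (FORSTER_PREFACTOR * kappa2 * medium.refractive_index ** -4
          * medium.donor_quantum_yield * J)
    return float(r6 ** (1.0 / 6.0))


def pair_rate(donor_pos: np.ndarray, donor_dip: np.ndarray,
              acceptor_pos: np.ndarray, acceptor_dip: np.ndarray,
              J: float, medium: MediumParams,
              prefactor: float = 1.0) -> float:
    """Förster rate donor→acceptor in ps⁻¹, k = pref · (1/τ_D)(R0/R)⁶."""
    r = np.asarray(acceptor_pos, float) - np.asarray(donor_pos, float)
    dist = np.linalg.norm(r)
    if dist == 0:
        raise ValueError("donor and acceptor positions coincide")
    k2 = kappa_squared(donor_dip, acceptor_dip, r)
    r0 = forster_radius(J, k2, medium)
    return prefactor / medium.donor_lifetime_ps * (r0 / dist) ** 6


@dataclass
class RateMatrix:
    """First-order kinetic matrix K (ps⁻¹) over lattice site order.

    ``K[i, j]`` (i≠j) is the transfer rate j→i; the diagonal closes the
    mass balance, so each column sums to −(decay_j + trap_j).
    """

    K: np.ndarray
    site_ids: np.ndarray
    decay: np.ndarray  # per-site decay rate, ps⁻¹
    trap: np.ndarray  # per-site trap rate, ps⁻¹
    meta: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.K.shape[0]

    def transfer_only(self) -> "RateMatrix":
        """Same network with decay and trap channels removed."""
        k = self.K.copy()
        np.fill_diagonal(k, 0.0)
        np.fill_diagonal(k, -k.sum(axis=0))
        return RateMatrix(K=k, site_ids=self.site_ids.copy(),
                          decay=np.zeros(self.n_sites),
                          trap=np.zeros(self.n_sites),
                          meta=dict(self.meta, transfer_only=True))

    def subnetwork(self, keep: np.ndarray) -> "RateMatrix":
        """Restriction to a subset of sites (e.g. the α-PCB sub-network).

        Off-diagonal transfer rates between retained sites are kept;
        diagonals are rebuilt so mass balance holds within the sub-network.
        """
        keep = np.asarray(keep, dtype=int)
        k = self.K[np.ix_(keep, keep)].copy()
        np.fill_diagonal(k, 0.0)
        decay = self.decay[keep].copy()
        trap = self.trap[keep].copy()
        np.fill_diagonal(k, -(k.sum(axis=0) + decay + trap))
        return RateMatrix(K=k, site_ids=self.site_ids[keep].copy(),
                          decay=decay, trap=trap,
                          meta=dict(self.meta, subnetwork=keep.tolist()))


def build_rate_matrix(lattice, spectra: dict[str, SpectralModel],
                      medium: MediumParams = MediumParams(),
                      decay: dict[str, float] | float | None = None,
                      trap: dict[int, float] | None = None,
                      prefactor: float = 1.0,
                      distance_cutoff: float | None = None) -> RateMatrix:
    """Full N×N Förster rate matrix for a chromophore lattice.

    Parameters
    ----------
    decay : per-class excited-state decay rate (ps⁻¹), a single rate, or
        None for no decay.
    trap : optional ``{site_id: rate}`` irreversible loss channels.
    prefactor : global dimensionless scale on every transfer rate.
    distance_cutoff : centre distance (Å) beyond which pairs are skipped;
        by default every pair is included.
    """
    pos = lattice.positions
    dip = lattice.dipoles
    classes = lattice.classes
    n = len(pos)
    # direction-specific overlap integrals J[donor_class][acceptor_class]
    J = {dc: {ac: overlap_integral(spectra[dc], spectra[ac])
              for ac in ("alpha", "beta")} for dc in ("alpha", "beta")}
    K = np.zeros((n, n))
    for j in range(n):
        for i in range(n):
            if i == j:
                continue
            r = pos[i] - pos[j]
            dist = np.linalg.norm(r)
            if distance_cutoff is not None and dist > distance_cutoff:
                continue
            K[i, j] = pair_rate(pos[j], dip[j], pos[i], dip[i],
                                J[classes[j]][classes[i]], medium, prefactor)
    if decay is None:
        decay_vec = np.zeros(n)
    elif isinstance(decay, dict):
        decay_vec = np.array([decay.get(c, 0.0) for c in classes])
    else:
        decay_vec = np.full(n, float(decay))
    trap_vec = np.zeros(n)
    if trap:
        for sid, rate in trap.items():
            if not 0 <= sid < n:
                raise ValueError(f"trap site_id {sid} not in lattice")
            trap_vec[sid] = rate
    np.fill_diagonal(K, -(K.sum(axis=0) + decay_vec + trap_vec))
    return RateMatrix(K=K, site_ids=np.arange(n), decay=decay_vec,
                      trap=trap_vec,
                      meta={"prefactor": prefactor,
                            "medium": {"n": medium.refractive_index,
                                       "phi_d": medium.donor_quantum_yield,
                                       "tau_d_ps": medium.donor_lifetime_ps}})
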