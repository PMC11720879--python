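"""Homogeneous 2D acoustic forward simulation on a circular sensor ring.

The wave model is the first-order k-space pseudospectral scheme: coupled
pressure/particle-velocity equations advanced with spectrally exact,
spatially staggered derivatives and a k-space dispersion correction
``kappa = sinc(c_ref * k * dt / 2)``, which makes plane waves propagate at
exactly the medium sound speed for a homogeneous medium.  A split-field
perfectly matched layer (PML) of 20 grid points is appended *outside* the
128 x 128 imaging region, so the full computational grid is 168 x 168 and
the 4 mm sensor ring lies entirely in the physical region.

The solver state is batched: a stack of B initial-pressure fields is
propagated in one pass (FFTs over the trailing axes), which is what makes
dataset generation on a single CPU practical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from .phantoms import GRID_SIZE, PIXEL_SIZE_M

__all__ = [
    "Grid2D",
    "Medium",
    "SensorArray",
    "SensorData",
    "build_sensor_array",
    "KSpaceSolver",
    "simulate_forward",
    "add_gaussian_noise",
]

RING_RADIUS_M = 4e-3
SENSOR_COUNT_RANGE = (8, 512)
#: PML absorption strength (nepers per grid point, k-Wave convention)
PML_ALPHA = 2.0


@dataclass(frozen=True)
class Medium:
    """Homogeneous, lossless acoustic medium."""

    sound_speed: float = 1500.0  # m/s
    density: float = 1000.0  # kg/m^3

    def __post_init__(self) -> None:
        if self.sound_speed <= 0 or self.density <= 0:
            raise ValueError("sound speed and density must be positive")


@dataclass(frozen=True)
class Grid2D:
    """Imaging grid plus time stepping parameters.

    The time step is set from the CFL stability bound ``dt = cfl * dx / c``
    (default CFL 0.3) and the window length covers 1.2 ring diameters of
    travel so every wavefront crosses the array.
    """

    nx: int = GRID_SIZE
    ny: int = GRID_SIZE
    dx: float = PIXEL_SIZE_M
    dy: float = PIXEL_SIZE_M
    pml_width: int = 20
    cfl: float = 0.3
    dt: float = 0.0  # filled from cfl when left at 0
    nt: int = 0  # filled from the ring-crossing window when left at 0

    def __post_init__(self) -> None:
        c = Medium().sound_speed
        if self.dt == 0.0:
            object.__setattr__(self, "dt", self.cfl * self.dx / c)
        if self.nt == 0:
            travel = 1.2 * (2.0 * RING_RADIUS_M)  # 1.2 x ring diameter
            object.__setattr__(self, "nt", int(np.ceil(travel / (c * self.dt))))
        if self.nx <= 0 or self.ny <= 0 or self.dx <= 0 or self.dy <= 0:
            raise ValueError("grid dimensions must be positive")

    def validate_dt(self, medium: Medium) -> None:
        """Reject a time step violating the CFL stability bound."""
        bound = 0.3 * min(self.dx, self.dy) / medium.sound_speed
        if self.dt > bound * (1 + 1e-12):
            raise ValueError(
                f"dt={self.dt:.3e}s violates the stability bound "
                f"CFL<=0.3 (max {bound:.3e}s at c={medium.sound_speed} m/s)"
            )

    @property
    def n_comp(self) -> tuple[int, int]:
        """Computational grid size including the exterior PML."""
        return (self.nx + 2 * self.pml_width, self.ny + 2 * self.pml_width)

    @property
    def interior(self) -> tuple[slice, slice]:
        w = self.pml_width
        return (slice(w, w + self.nx), slice(w, w + self.ny))


@dataclass(frozen=True)
class SensorArray:
    """Point transducers on a circle, snapped to the nearest grid node.

    ``rows``/``cols`` are indices on the *computational* grid (PML
    included); duplicate nodes are possible for dense arrays and are kept
    as separate channels.
    """

    n_sensors: int
    ring_radius: float
    angles: np.ndarray
    rows: np.ndarray
    cols: np.ndarray

    def grid_key(self, grid: Grid2D) -> tuple[int, int]:
        return grid.n_comp


def build_sensor_array(
    n_sensors: int, grid: Grid2D | None = None, ring_radius: float = RING_RADIUS_M
) -> SensorArray:
    """Place ``n_sensors`` transducers uniformly on the ring.

    Angle ``i`` is ``2*pi*i/n``; each position is mapped to the nearest
    computational-grid node relative to the grid centre.
    """
    lo, hi = SENSOR_COUNT_RANGE
    if not lo <= n_sensors <= hi:
        raise ValueError(f"n_sensors must be in [{lo}, {hi}], got {n_sensors}")
    if grid is None:
        grid = Grid2D()
    angles = 2.0 * np.pi * np.arange(n_sensors) / n_sensors
    r_px = ring_radius / grid.dx
    c_row = grid.pml_width + grid.nx // 2
    c_col = grid.pml_width + grid.ny // 2
    exact_r = c_row + r_px * np.sin(angles)
    exact_c = c_col + r_px * np.cos(angles)
    # snap to a surrounding node within half a pixel of the nominal ring
    # radius, preferring the node closest to the exact position (small
    # angular jitter) among those that satisfy the radial bound
    cand_r = np.stack([np.floor(exact_r), np.floor(exact_r) + 1] * 2)
    cand_c = np.stack([np.floor(exact_c)] * 2 + [np.floor(exact_c) + 1] * 2)
    radial_err = np.abs(np.hypot(cand_r - c_row, cand_c - c_col) - r_px)
    prox = np.hypot(cand_r - exact_r, cand_c - exact_c)
    # nodes violating the radial bound are heavily penalised; ties among
    # admissible nodes resolve by proximity
    score = np.where(radial_err <= 0.5, prox, 1e3 + radial_err)
    best = np.argmin(score, axis=0)
    rows = cand_r[best, np.arange(n_sensors)].astype(np.intp)
    cols = cand_c[best, np.arange(n_sensors)].astype(np.intp)
    w = grid.pml_width
    if (
        rows.min() < w
        or cols.min() < w
        or rows.max() >= w + grid.nx
        or cols.max() >= w + grid.ny
    ):
        raise ValueError("sensor ring does not fit inside the non-PML region")
    return SensorArray(n_sensors, ring_radius, angles, rows, cols)


@dataclass
class SensorData:
    """Multichannel pressure time series (the sinogram)."""

    series: np.ndarray  # (n_sensors, nt)
    dt: float
    snr_db: float | None = None
    n_sensors: int = field(init=False)

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=np.float64)
        if self.series.ndim != 2:
            raise ValueError("series must be (n_sensors, nt)")
        if not np.all(np.isfinite(self.series)):
            raise ValueError("sensor series contains non-finite values")
        self.n_sensors = self.series.shape[0]


def _blackman_smooth(field_k: np.ndarray, n: tuple[int, int]) -> np.ndarray:
    """Frequency-domain Blackman window (applied to the field's half-spectrum
    real FFT) used to suppress Gibbs ringing from a discontinuous initial
    pressure."""
    wins = []
    for size in n:
        w = np.blackman(size + 1)[:size]
        wins.append(np.fft.ifftshift(w))
    return field_k * wins[0][:, None] * wins[1][None, : n[1] // 2 + 1]


class KSpaceSolver:
    """Batched first-order k-space pseudospectral solver.

    Parameters
    ----------
    grid, medium : discretisation and acoustic properties.
    use_pml : apply the exterior split-field PML (disable for periodic,
        energy-conserving propagation, used by the conservation checks).
    smooth_p0 : apply the k-space Blackman smoothing to initial pressure.
    """

    def __init__(
        self,
        grid: Grid2D,
        medium: Medium,
        use_pml: bool = True,
        smooth_p0: bool = True,
        dtype=np.float64,
    ) -> None:
        grid.validate_dt(medium)
        self.grid = grid
        self.medium = medium
        self.use_pml = use_pml
        self.smooth_p0 = smooth_p0
        self.dtype = np.dtype(dtype)
        cdtype = np.complex64 if self.dtype == np.float32 else np.complex128
        nx_c, ny_c = grid.n_comp
        ny_h = ny_c // 2 + 1  # half spectrum (real FFT along the last axis)
        kx = 2.0 * np.pi * np.fft.fftfreq(nx_c, grid.dx)
        ky = 2.0 * np.pi * np.fft.rfftfreq(ny_c, grid.dy)
        k = np.sqrt(kx[:, None] ** 2 + ky[None, :] ** 2)
        c, dt = medium.sound_speed, grid.dt
        kappa = np.sinc(c * k * dt / (2.0 * np.pi))  # sinc(x)=sin(pi x)/(pi x)
        # spatially staggered spectral derivative operators (half spectrum)
        self._ddx_pos = (1j * kx[:, None] * kappa * np.exp(1j * kx[:, None] * grid.dx / 2)).astype(cdtype)
        self._ddx_neg = (1j * kx[:, None] * kappa * np.exp(-1j * kx[:, None] * grid.dx / 2)).astype(cdtype)
        self._ddy_pos = (1j * ky[None, :] * kappa * np.exp(1j * ky[None, :] * grid.dy / 2)).astype(cdtype)
        self._ddy_neg = (1j * ky[None, :] * kappa * np.exp(-1j * ky[None, :] * grid.dy / 2)).astype(cdtype)
        # the Nyquist bin has no odd-symmetric partner: zero it so the
        # staggered derivative of a real field stays real (and adjoint)
        for op in (self._ddx_pos, self._ddx_neg):
            op[nx_c // 2, :] = 0.0
        for op in (self._ddy_pos, self._ddy_neg):
            op[:, ny_h - 1] = 0.0
        self._pml = self._build_pml()

    def _pml_profile(self, n: int, staggered: bool) -> np.ndarray:
        """1D PML damping factor exp(-alpha * dt / 2) with a quartic ramp."""
        g = self.grid
        w = g.pml_width
        x = np.arange(n, dtype=np.float64)
        if staggered:
            x = x + 0.5
        dist = np.zeros(n)
        left = x < w
        right = x > n - 1 - w
        dist[left] = (w - x[left]) / w
        dist[right] = (x[right] - (n - 1 - w)) / w
        alpha = PML_ALPHA * (self.medium.sound_speed / g.dx) * dist**4
        return np.exp(-alpha * g.dt / 2.0)

    def _build_pml(self) -> dict[str, np.ndarray]:
        nx_c, ny_c = self.grid.n_comp
        if not self.use_pml:
            one_x = np.ones((nx_c, 1), dtype=self.dtype)
            one_y = np.ones((1, ny_c), dtype=self.dtype)
            return {"x": one_x, "x_sg": one_x, "y": one_y, "y_sg": one_y}
        return {
            "x": self._pml_profile(nx_c, False)[:, None].astype(self.dtype),
            "x_sg": self._pml_profile(nx_c, True)[:, None].astype(self.dtype),
            "y": self._pml_profile(ny_c, False)[None, :].astype(self.dtype),
            "y_sg": self._pml_profile(ny_c, True)[None, :].astype(self.dtype),
        }

    # -- helpers ---------------------------------------------------------
    def embed(self, p0: np.ndarray) -> np.ndarray:
        """Zero-pad (B, nx, ny) imaging fields into the computational grid."""
        p0 = np.atleast_3d(np.asarray(p0, dtype=self.dtype))
        if p0.ndim == 3 and p0.shape[1:] == (self.grid.nx, self.grid.ny):
            batch = p0
        elif p0.shape == (self.grid.nx, self.grid.ny, 1):  # atleast_3d artefact
            batch = np.moveaxis(p0, -1, 0)
        else:
            raise ValueError("p0 must be (nx, ny) or (B, nx, ny)")
        full = np.zeros((batch.shape[0],) + self.grid.n_comp, dtype=self.dtype)
        full[(slice(None),) + self.grid.interior] = batch
        return full

    def _smooth(self, p: np.ndarray) -> np.ndarray:
        pk = sfft.rfft2(p, axes=(-2, -1))
        pk = _blackman_smooth(pk, self.grid.n_comp)
        return sfft.irfft2(pk, axes=(-2, -1), s=self.grid.n_comp).astype(
            self.dtype, copy=False
        )

    def _grad(self, f: np.ndarray, op_x: np.ndarray, op_y: np.ndarray):
        """Spectral x/y derivatives of a real field (one rfft, two irffts)."""
        shape = self.grid.n_comp
        fk = sfft.rfft2(f, axes=(-2, -1))
        dfdx = sfft.irfft2(op_x * fk, axes=(-2, -1), s=shape)
        dfdy = sfft.irfft2(op_y * fk, axes=(-2, -1), s=shape)
        return dfdx, dfdy

    def _div(self, ux: np.ndarray, uy: np.ndarray):
        """x-derivative of ux and y-derivative of uy (two rffts, two irffts)."""
        shape = self.grid.n_comp
        duxdx = sfft.irfft2(
            self._ddx_neg * sfft.rfft2(ux, axes=(-2, -1)), axes=(-2, -1), s=shape
        )
        duydy = sfft.irfft2(
            self._ddy_neg * sfft.rfft2(uy, axes=(-2, -1)), axes=(-2, -1), s=shape
        )
        return duxdx, duydy

    # -- forward ---------------------------------------------------------
    def run_forward(
        self,
        p0: np.ndarray,
        sensors: SensorArray,
        record_energy: bool = False,
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """Propagate initial pressure(s) and record the sensor channels.

        Returns ``(series, energy)`` where series is (B, n_sensors, nt)
        and energy (if requested) is (B, nt).  The energy reported for
        step ``n >= 1`` is the exact leapfrog invariant of the staggered
        scheme, ``rho0/2 * ||u^(n-1/2)||^2 + <p^(n-1), p^n> / (2 rho0 c^2)``;
        entry 0 is the potential energy of the initial condition (which
        differs from the invariant by the injection transient).
        """
        g, med = self.grid, self.medium
        c2 = med.sound_speed**2
        rho0, dt = med.density, g.dt
        pml = self._pml
        p = self.embed(p0)
        if self.smooth_p0:
            p = self._smooth(p)
        B = p.shape[0]
        rhox = p / (2.0 * c2)
        rhoy = p / (2.0 * c2)
        ux = np.zeros_like(p)
        uy = np.zeros_like(p)
        series = np.empty((B, sensors.n_sensors, g.nt), dtype=np.float64)
        energy = np.empty((B, g.nt), dtype=np.float64) if record_energy else None
        cell = g.dx * g.dy
        series[:, :, 0] = p[:, sensors.rows, sensors.cols]
        if record_energy:
            energy[:, 0] = (
                np.sum(p**2, axis=(-2, -1)) / (2.0 * rho0 * c2) * cell
            )
        for n in range(1, g.nt):
            dpdx, dpdy = self._grad(p, self._ddx_pos, self._ddy_pos)
            # first step advances u by dt/2 only (staggered-start correction)
            du_scale = dt if n > 1 else dt / 2.0
            ux = pml["x_sg"] * (pml["x_sg"] * ux - du_scale / rho0 * dpdx)
            uy = pml["y_sg"] * (pml["y_sg"] * uy - du_scale / rho0 * dpdy)
            p_prev = p
            duxdx, duydy = self._div(ux, uy)
            rhox = pml["x"] * (pml["x"] * rhox - dt * rho0 * duxdx)
            rhoy = pml["y"] * (pml["y"] * rhoy - dt * rho0 * duydy)
            p = c2 * (rhox + rhoy)
            series[:, :, n] = p[:, sensors.rows, sensors.cols]
            if record_energy:
                energy[:, n] = (
                    np.sum(p_prev * p, axis=(-2, -1)) / (2.0 * rho0 * c2)
                    + 0.5 * rho0 * np.sum(ux**2 + uy**2, axis=(-2, -1))
                ) * cell
        return series, energy

    # -- time reversal ---------------------------------------------------
    def run_time_reversal(self, series: np.ndarray, sensors: SensorArray) -> np.ndarray:
        """Re-emit recorded series in reversed time as enforced (Dirichlet)
        pressure values at the sensor nodes; returns the final interior
        pressure fields (B, nx, ny), un-normalised."""
        series = np.asarray(series, dtype=np.float64)
        if series.ndim == 2:
            series = series[None]
        B, m, nt = series.shape
        if m != sensors.n_sensors:
            raise ValueError("series channel count does not match the sensor array")
        g, med = self.grid, self.medium
        c2 = med.sound_speed**2
        rho0, dt = med.density, g.dt
        pml = self._pml
        series = series.astype(self.dtype, copy=False)
        shape = (B,) + g.n_comp
        p = np.zeros(shape, dtype=self.dtype)
        rhox = np.zeros(shape, dtype=self.dtype)
        rhoy = np.zeros(shape, dtype=self.dtype)
        ux = np.zeros(shape, dtype=self.dtype)
        uy = np.zeros(shape, dtype=self.dtype)
        # duplicate sensor nodes (dense arrays): average enforced values
        flat_idx = sensors.rows * g.n_comp[1] + sensors.cols
        uniq, inv = np.unique(flat_idx, return_inverse=True)
        counts = np.bincount(inv).astype(np.float64)
        urows, ucols = np.divmod(uniq, g.n_comp[1])

        def enforce(t_rev: int) -> None:
            vals = np.zeros((B, uniq.size), dtype=self.dtype)
            np.add.at(vals, (slice(None), inv), series[:, :, t_rev])
            vals /= counts
            p[:, urows, ucols] = vals
            rhox[:, urows, ucols] = vals / (2.0 * c2)
            rhoy[:, urows, ucols] = vals / (2.0 * c2)

        enforce(nt - 1)
        for n in range(1, nt):
            dpdx, dpdy = self._grad(p, self._ddx_pos, self._ddy_pos)
            du_scale = dt if n > 1 else dt / 2.0
            ux = pml["x_sg"] * (pml["x_sg"] * ux - du_scale / rho0 * dpdx)
            uy = pml["y_sg"] * (pml["y_sg"] * uy - du_scale / rho0 * dpdy)
            duxdx, duydy = self._div(ux, uy)
            rhox = pml["x"] * (pml["x"] * rhox - dt * rho0 * duxdx)
            rhoy = pml["y"] * (pml["y"] * rhoy - dt * rho0 * duydy)
            p = c2 * (rhox + rhoy)
            enforce(nt - 1 - n)
        return p[(slice(None),) + g.interior]


def simulate_forward(
    p0: np.ndarray,
    grid: Grid2D,
    medium: Medium,
    sensors: SensorArray,
    smooth_p0: bool = True,
    use_pml: bool = True,
) -> SensorData:
    """Record the pressure time series of one initial-pressure field on the
    sensor ring (convenience wrapper over :class:`KSpaceSolver`)."""
    p0 = np.asarray(p0, dtype=np.float64)
    if p0.shape != (grid.nx, grid.ny):
        raise ValueError(f"p0 shape {p0.shape} does not match grid {(grid.nx, grid.ny)}")
    solver = KSpaceSolver(grid, medium, use_pml=use_pml, smooth_p0=smooth_p0)
    series, _ = solver.run_forward(p0, sensors)
    return SensorData(series[0], grid.dt, snr_db=None)


def add_gaussian_noise(
    data: SensorData,
    rng: np.random.Generator,
    snr_db_range: tuple[float, float] = (40.0, 60.0),
) -> SensorData:
    """Add white Gaussian sensor noise at a target SNR drawn uniformly from
    ``snr_db_range`` (dB).

    The noise variance is set from the global mean-square of the clean
    multichannel signal (one variance for all channels); the recorded
    ``snr_db`` is recomputed from the noise actually added.
    """
    p_signal = float(np.mean(data.series**2))
    if p_signal == 0.0:
        raise ValueError("SNR undefined for an all-zero signal")
    lo, hi = snr_db_range
    if lo > hi:
        raise ValueError("snr_db_range must be (low, high)")
    if np.isinf(lo):  # infinite SNR limit: no noise
        return SensorData(data.series.copy(), data.dt, snr_db=np.inf)
    target_db = float(rng.uniform(lo, hi))
    noise_var = p_signal / 10.0 ** (target_db / 10.0)
    noise = rng.normal(0.0, np.sqrt(noise_var), size=data.series.shape)
    realized = 10.0 * np.log10(p_signal / float(np.mean(noise**2)))
    return SensorData(data.series + noise, data.dt, snr_db=float(realized))
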