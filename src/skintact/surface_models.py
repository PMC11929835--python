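"""Stimulus geometry and roughness mathematics.

Two stimulus families are modelled: hexagonal lattices of bendable
micropillars moulded into a soft elastomer, and hard plastic plates carrying
self-affine randomly rough topographies.  The module provides the closed-form
lattice density and pillar bending stiffness, spectral synthesis of
self-affine height maps, and the RMS curvature used to quantify roughness at
the scale of the finger ridges.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MicropillarSample",
    "HeightMap",
    "PILLAR_SAMPLES",
    "ROUGH_SAMPLES",
    "ROUGH_SAMPLE_CURVATURE",
    "ROUGH_SAMPLE_HURST",
    "FIBRIL_SAMPLES",
    "DEFAULT_MODULUS_PA",
    "pillar_density",
    "bending_stiffness",
    "synthesize_self_affine_surface",
    "rms_curvature",
    "write_height_map",
    "read_height_map",
]

#: Elastic modulus of the micro-structured rubber (polyurethane), Pa.
DEFAULT_MODULUS_PA = 1.7e6


@dataclass(frozen=True)
class MicropillarSample:
    """One micropillar geometry, labelled ``"<D>/<L>"`` in micrometres.

    Pillars sit on a hexagonal lattice with centre-to-centre spacing equal to
    twice the diameter.
    """

    label: str
    diameter_um: float
    height_um: float
    modulus_pa: float = DEFAULT_MODULUS_PA

    def __post_init__(self) -> None:
        if self.diameter_um <= 0 or self.height_um <= 0:
            raise ValueError("pillar diameter and height must be positive")
        if self.modulus_pa <= 0:
            raise ValueError("elastic modulus must be positive")

    @property
    def spacing_um(self) -> float:
        return 2.0 * self.diameter_um

    @property
    def aspect_ratio(self) -> float:
        return self.height_um / self.diameter_um


#: The six micropillar geometries of the rubber sample set (diameter/height, µm).
PILLAR_SAMPLES: tuple[MicropillarSample, ...] = tuple(
    MicropillarSample(f"{d}/{h}", d, h)
    for d, h in [(40, 120), (100, 100), (100, 200), (100, 300), (150, 150), (150, 350)]
)

#: Labels of the pillar samples with aspect ratio > 1 (the compliant,
#: "fibrillar" surfaces entering the µ_fibril composite).
FIBRIL_SAMPLES: tuple[str, ...] = tuple(
    s.label for s in PILLAR_SAMPLES if s.aspect_ratio > 1
)

#: Labels of the six randomly rough plastic samples.
ROUGH_SAMPLES: tuple[str, ...] = ("S01", "S02", "S03", "S07", "S08", "S09")

#: Measured RMS curvature of each rough sample, mm^-1.  These are properties
#: of the manufactured sample set, shipped as constants.
ROUGH_SAMPLE_CURVATURE: dict[str, float] = dict(
    zip(ROUGH_SAMPLES, (3.29, 3.03, 1.93, 1.76, 1.09, 1.00))
)

#: Nominal Hurst exponent of each rough sample (higher H -> smoother at small
#: scale, hence lower RMS curvature at fixed Sq).
ROUGH_SAMPLE_HURST: dict[str, float] = dict(
    zip(ROUGH_SAMPLES, (0.4, 0.4, 0.6, 0.6, 0.8, 0.8))
)


def pillar_density(diameter_um: float) -> float:
    """Areal pillar density of a hexagonal lattice, mm^-2.

    The lattice constant is twice the pillar diameter, so the unit cell has
    area ``sqrt(3)/2 * (2D)^2 = 2*sqrt(3)*D^2`` and the density is
    ``1 / (2*sqrt(3)*D^2)`` with ``D`` in mm.  For D = 40 µm this evaluates
    to 180 mm^-2, for D = 150 µm to 12.8 mm^-2.
    """
    if diameter_um <= 0:
        raise ValueError("pillar diameter must be positive")
    d_mm = diameter_um * 1e-3
    return 1.0 / (2.0 * np.sqrt(3.0) * d_mm**2)


def bending_stiffness(sample: MicropillarSample) -> float:
    """Lateral force per bending angle of one pillar, N/rad.

    A pillar of diameter D and height L loaded laterally at its top behaves
    as a clamped cylindrical beam: F_L / theta = pi * E * D^4 / (32 * L^2),
    evaluated in SI units.  Stiffness grows as D^4 and falls as L^-2, so the
    short wide 150/150 pillars are the stiffest of the set and the thin tall
    40/120 pillars the most bendable.
    """
    d = sample.diameter_um * 1e-6
    length = sample.height_um * 1e-6
    return np.pi * sample.modulus_pa * d**4 / (32.0 * length**2)


@dataclass
class HeightMap:
    """Square-grid surface topography with uniform spacing ``dx`` (mm)."""

    heights: np.ndarray
    dx: float
    nominal_sq: float | None = None
    hurst: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("height map must be a 2-D grid")
        if self.dx <= 0:
            raise ValueError("grid spacing must be positive")
        if self.hurst is not None and not (0.0 < self.hurst < 1.0):
            raise ValueError("Hurst exponent must lie in (0, 1)")

    @property
    def rms_roughness(self) -> float:
        h = self.heights
        return float(np.sqrt(np.mean((h - h.mean()) ** 2)))


def synthesize_self_affine_surface(
    sq: float,
    hurst: float,
    n_grid: int,
    dx: float,
    seed: int,
    short_cutoff: float = 0.5,
    long_cutoff: float | None = None,
) -> HeightMap:
    """Spectral synthesis of an isotropic self-affine rough surface.

    The two-dimensional power spectrum is proportional to ``q^(-2-2H)``
    between a long-wavelength cutoff (default: the grid size) and a
    short-wavelength cutoff (default 0.5 mm, the smallest wavelength present
    on the physical samples); outside the passband the spectrum is zero.
    Fourier components get independent Gaussian amplitudes and uniform random
    phases, and the result is rescaled so the measured RMS roughness equals
    ``sq`` exactly.

    Parameters
    ----------
    sq : target RMS roughness, mm.
    hurst : Hurst exponent in (0, 1).
    n_grid : grid points per side; must be a power of two.
    dx : grid spacing, mm.
    seed : RNG seed for amplitudes and phases.
    short_cutoff, long_cutoff : passband wavelength limits, mm.
    """
    if not (0.0 < hurst < 1.0):
        raise ValueError("Hurst exponent must lie in (0, 1)")
    if n_grid < 4 or (n_grid & (n_grid - 1)) != 0:
        raise ValueError("n_grid must be a power of two >= 4")
    size = n_grid * dx
    if long_cutoff is None:
        long_cutoff = size
    nyquist_wavelength = 2.0 * dx
    if short_cutoff < nyquist_wavelength or long_cutoff > size + 1e-12:
        raise ValueError(
            "wavelength cutoffs must lie between the Nyquist wavelength "
            f"({nyquist_wavelength:g} mm) and the grid size ({size:g} mm)"
        )
    if short_cutoff >= long_cutoff:
        raise ValueError("short_cutoff must be smaller than long_cutoff")

    rng = np.random.default_rng(seed)
    q = 2.0 * np.pi * np.fft.fftfreq(n_grid, d=dx)
    qx, qy = np.meshgrid(q, q, indexing="ij")
    qr = np.hypot(qx, qy)
    q_lo = 2.0 * np.pi / long_cutoff
    q_hi = 2.0 * np.pi / short_cutoff

    amp = np.zeros_like(qr)
    band = (qr >= q_lo) & (qr <= q_hi)
    amp[band] = qr[band] ** (-(1.0 + hurst))  # sqrt of PSD ~ q^(-2-2H)

    spectrum = amp * (rng.normal(size=qr.shape) + 1j * rng.normal(size=qr.shape))
    h = np.fft.ifft2(spectrum).real
    h -= h.mean()
    rms = np.sqrt(np.mean(h**2))
    if rms == 0.0:
        raise ValueError("degenerate spectrum: empty passband")
    h *= sq / rms
    return HeightMap(
        h, dx, nominal_sq=sq, hurst=hurst,
        meta={"seed": seed, "short_cutoff": short_cutoff, "long_cutoff": long_cutoff},
    )


def rms_curvature(height_map: HeightMap, axis: int | None = None) -> float:
    """RMS curvature of a height map, mm^-1.

    Second derivatives are taken by central differences on interior nodes.
    With ``axis=None`` (default) the two principal directions are averaged:
    sqrt( (mean(h_xx^2) + mean(h_yy^2)) / 2 ).  With ``axis=0`` or ``1`` the
    RMS of the second derivative along that axis alone is returned (for a
    1-D sinusoid A*sin(q x) this is A*q^2/sqrt(2)).

    Adding any plane a + b*x + c*y to the height map leaves the result
    unchanged, since second differences annihilate affine terms.
    """
    h = height_map.heights
    if h.shape[0] < 3 or h.shape[1] < 3:
        raise ValueError("RMS curvature needs a grid of at least 3x3 nodes")
    dx2 = height_map.dx**2
    hxx = (h[2:, 1:-1] - 2.0 * h[1:-1, 1:-1] + h[:-2, 1:-1]) / dx2
    hyy = (h[1:-1, 2:] - 2.0 * h[1:-1, 1:-1] + h[1:-1, :-2]) / dx2
    if axis == 0:
        return float(np.sqrt(np.mean(hxx**2)))
    if axis == 1:
        return float(np.sqrt(np.mean(hyy**2)))
    if axis is not None:
        raise ValueError("axis must be 0, 1 or None")
    return float(np.sqrt(0.5 * (np.mean(hxx**2) + np.mean(hyy**2))))


def write_height_map(height_map: HeightMap, path) -> None:
    """Write a height map as plain-matrix CSV with a small comment header."""
    header = [f"# dx_mm={height_map.dx!r}"]
    if height_map.nominal_sq is not None:
        header.append(f"# Sq_mm={height_map.nominal_sq!r}")
    if height_map.hurst is not None:
        header.append(f"# H={height_map.hurst!r}")
    buf = io.StringIO()
    np.savetxt(buf, height_map.heights, delimiter=",")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(header) + "\n")
        fh.write(buf.getvalue())


def read_height_map(path) -> HeightMap:
    meta: dict[str, float] = {}
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key] = float(value)
            else:
                rows.append([float(v) for v in line.split(",")])
    if "dx_mm" not in meta:
        raise ValueError("height-map file lacks the dx_mm header")
    return HeightMap(
        np.asarray(rows), meta["dx_mm"],
        nominal_sq=meta.get("Sq_mm"), hurst=meta.get("H"),
    )
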