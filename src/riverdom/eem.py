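"""Excitation-emission matrix (EEM) data model, I/O and preprocessing.

An EEM is a grid of fluorescence intensities measured over excitation
(rows) and emission (columns) wavelengths. Preprocessing follows the
standard chain for dissolved-organic-matter fluorimetry: blank
subtraction, optional absorbance-based inner-filter correction,
excision of Rayleigh/Raman scatter ridges, and normalisation to Raman
units using the integrated water Raman peak of a pure-water blank at
excitation 350 nm (emission 371-428 nm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Raman shift of the water OH-stretch band used to locate the Raman
#: scatter ridge, in cm^-1.
RAMAN_SHIFT_CM = 3400.0

#: Emission window (nm) of the water Raman band at excitation 350 nm
#: used for Raman-unit normalisation.
RAMAN_EX_NM = 350.0
RAMAN_EM_LO_NM = 371.0
RAMAN_EM_HI_NM = 428.0


class EEMError(ValueError):
    """Raised on malformed EEM data or incompatible operands."""


@dataclass
class EEMSpectrum:
    """One sample's excitation x emission intensity grid.

    Attributes
    ----------
    ex, em:
        Strictly increasing wavelength axes in nm.
    intensity:
        ``(len(ex), len(em))`` matrix of fluorescence intensities.
    mask:
        Boolean matrix of the same shape; ``True`` marks excised or
        missing cells that are excluded from downstream sums and fits.
    units:
        ``"raw"`` (instrument counts) or ``"raman_unit"``.
    sample_id:
        Free-text identifier.
    """

    ex: np.ndarray
    em: np.ndarray
    intensity: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    units: str = "raw"
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.ex = np.asarray(self.ex, dtype=float)
        self.em = np.asarray(self.em, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.intensity.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.ex.ndim != 1 or self.em.ndim != 1:
            raise EEMError("wavelength axes must be one-dimensional")
        if np.any(np.diff(self.ex) <= 0):
            raise EEMError("excitation axis must be strictly increasing")
        if np.any(np.diff(self.em) <= 0):
            raise EEMError("emission axis must be strictly increasing")
        if self.intensity.shape != (self.ex.size, self.em.size):
            raise EEMError(
                f"intensity shape {self.intensity.shape} does not match axes "
                f"({self.ex.size}, {self.em.size})"
            )
        if self.mask.shape != self.intensity.shape:
            raise EEMError("mask shape does not match intensity")

    # -- convenience -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def copy(self) -> "EEMSpectrum":
        return EEMSpectrum(
            ex=self.ex.copy(),
            em=self.em.copy(),
            intensity=self.intensity.copy(),
            mask=self.mask.copy(),
            units=self.units,
            sample_id=self.sample_id,
        )

    def masked_intensity(self) -> np.ndarray:
        """Intensity with excised cells set to NaN."""
        out = self.intensity.copy()
        out[self.mask] = np.nan
        return out

    def value_at(self, ex: float, em: float) -> float:
        """Bilinear interpolation of intensity at (ex, em) nm.

        Extrapolation outside the measured grid is refused.
        """
        if not (self.ex[0] <= ex <= self.ex[-1]):
            raise EEMError(f"excitation {ex} nm outside grid "
                           f"[{self.ex[0]}, {self.ex[-1]}]")
        if not (self.em[0] <= em <= self.em[-1]):
            raise EEMError(f"emission {em} nm outside grid "
                           f"[{self.em[0]}, {self.em[-1]}]")
        i = int(np.clip(np.searchsorted(self.ex, ex) - 1, 0, self.ex.size - 2))
        j = int(np.clip(np.searchsorted(self.em, em) - 1, 0, self.em.size - 2))
        x0, x1 = self.ex[i], self.ex[i + 1]
        y0, y1 = self.em[j], self.em[j + 1]
        tx = 0.0 if x1 == x0 else (ex - x0) / (x1 - x0)
        ty = 0.0 if y1 == y0 else (em - y0) / (y1 - y0)
        z = self.intensity
        return float(
            z[i, j] * (1 - tx) * (1 - ty)
            + z[i + 1, j] * tx * (1 - ty)
            + z[i, j + 1] * (1 - tx) * ty
            + z[i + 1, j + 1] * tx * ty
        )

    def emission_band_area(self, ex: float, em_lo: float, em_hi: float) -> float:
        """Trapezoidal integral over emission [em_lo, em_hi] at excitation ex.

        Band endpoints are linearly interpolated onto the native grid.
        """
        pts = [em_lo] + [
            float(w) for w in self.em if em_lo < w < em_hi
        ] + [em_hi]
        vals = [self.value_at(ex, w) for w in pts]
        return float(np.trapezoid(vals, pts))


@dataclass
class AbsorbanceSpectrum:
    """Absorbance per cm over wavelength (nm), for inner-filter correction."""

    wavelength: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if np.any(np.diff(self.wavelength) <= 0):
            raise EEMError("absorbance wavelengths must be strictly increasing")
        if np.any(self.absorbance < 0):
            raise EEMError("absorbance must be nonnegative")

    def at(self, nm: np.ndarray) -> np.ndarray:
        nm = np.atleast_1d(np.asarray(nm, dtype=float))
        lo, hi = self.wavelength[0], self.wavelength[-1]
        bad = (nm < lo) | (nm > hi)
        if np.any(bad):
            raise EEMError(
                f"absorbance spectrum does not cover {nm[bad][0]:g} nm "
                f"(range {lo:g}-{hi:g})"
            )
        return np.interp(nm, self.wavelength, self.absorbance)


# ---------------------------------------------------------------------------
# File I/O
#
# Dialect: comma-separated, UTF-8; the first cell is blank, the first row
# holds the emission wavelengths (nm) and the first column the excitation
# wavelengths (nm).
# ---------------------------------------------------------------------------

def read_eem(path, sample_id: str | None = None) -> EEMSpectrum:
    """Read an EEM from a CSV grid file (see module dialect)."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise EEMError(f"{path}: need a header row and at least one data row")
    header = lines[0].split(",")
    try:
        em = np.array([float(v) for v in header[1:]])
    except ValueError as exc:
        raise EEMError(f"{path}: bad emission header: {exc}") from exc
    rows, ex = [], []
    for r, ln in enumerate(lines[1:], start=2):
        cells = ln.split(",")
        if len(cells) != em.size + 1:
            raise EEMError(
                f"{path}: row {r} has {len(cells) - 1} values, "
                f"expected {em.size}"
            )
        try:
            ex.append(float(cells[0]))
            rows.append([float(v) for v in cells[1:]])
        except ValueError as exc:
            raise EEMError(f"{path}: row {r}: {exc}") from exc
    sid = sample_id if sample_id is not None else str(path)
    return EEMSpectrum(ex=np.array(ex), em=em, intensity=np.array(rows),
                       sample_id=sid)


def write_eem(eem: EEMSpectrum, path) -> None:
    """Write an EEM in the CSV grid dialect at full float precision."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("," + ",".join(repr(float(w)) for w in eem.em) + "\n")
        for i, x in enumerate(eem.ex):
            row = ",".join(repr(float(v)) for v in eem.intensity[i])
            fh.write(f"{repr(float(x))},{row}\n")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _check_same_axes(a: EEMSpectrum, b: EEMSpectrum) -> None:
    if a.ex.size != b.ex.size or not np.allclose(a.ex, b.ex):
        raise EEMError(
            "excitation axes differ: "
            f"{a.ex[:3]}... vs {b.ex[:3]}..."
        )
    if a.em.size != b.em.size or not np.allclose(a.em, b.em):
        raise EEMError(
            "emission axes differ: "
            f"{a.em[:3]}... vs {b.em[:3]}..."
        )


def subtract_blank(sample: EEMSpectrum, blank: EEMSpectrum) -> EEMSpectrum:
    """Subtract a pure-water blank EEM; negative residuals are kept."""
    _check_same_axes(sample, blank)
    out = sample.copy()
    out.intensity = sample.intensity - blank.intensity
    out.mask = sample.mask | blank.mask
    return out


def inner_filter_correct(eem: EEMSpectrum,
                         absorbance: AbsorbanceSpectrum) -> EEMSpectrum:
    """Absorbance-based inner-filter correction.

    Each cell is multiplied by ``10 ** ((A(ex) + A(em)) / 2)`` with the
    absorbance linearly interpolated at both wavelengths (1 cm path).
    """
    a_ex = absorbance.at(eem.ex)[:, None]
    a_em = absorbance.at(eem.em)[None, :]
    out = eem.copy()
    out.intensity = eem.intensity * 10.0 ** ((a_ex + a_em) / 2.0)
    return out


def raman_emission_center(ex_nm: float,
                          shift_cm: float = RAMAN_SHIFT_CM) -> float:
    """Emission wavelength (nm) of the water Raman band for a given excitation.

    The band sits at a constant wavenumber shift below the excitation line:
    1/em = 1/ex - shift.
    """
    inv = 1.0 / ex_nm - shift_cm * 1e-7
    return 1.0 / inv


def remove_scatter(eem: EEMSpectrum, w1: float = 10.0, w2: float = 10.0,
                   raman_halfwidth: float = 15.0,
                   raman_shift_cm: float = RAMAN_SHIFT_CM,
                   fill: str = "mask") -> EEMSpectrum:
    """Excise Rayleigh (first/second order) and Raman scatter ridges.

    Cells with ``|em - ex| <= w1`` (first-order Rayleigh),
    ``|em - 2 ex| <= w2`` (second order), or emission inside the Raman band
    for that excitation row are excised.  The physically meaningless
    region ``em < ex`` is always masked.

    Parameters
    ----------
    fill:
        ``"mask"`` marks excised cells missing; ``"interpolate"``
        replaces them by linear interpolation along the emission axis
        from the nearest surviving neighbours (rows with no survivor
        fall back to masking, with a warning).
    """
    if w1 < 0 or w2 < 0 or raman_halfwidth < 0:
        raise EEMError("scatter widths must be nonnegative")
    if fill not in ("mask", "interpolate"):
        raise EEMError(f"unknown fill mode {fill!r}")
    out = eem.copy()
    ex = eem.ex[:, None]
    em = eem.em[None, :]
    excise = (np.abs(em - ex) <= w1) | (np.abs(em - 2.0 * ex) <= w2)
    centers = np.array([raman_emission_center(x, raman_shift_cm)
                        for x in eem.ex])[:, None]
    excise |= np.abs(em - centers) <= raman_halfwidth
    below = em < ex  # anti-Stokes region: always masked, never interpolated
    if fill == "mask":
        out.mask = out.mask | excise | below
        return out
    for i in range(eem.ex.size):
        row_exc = excise[i] & ~below[i]
        good = ~row_exc & ~below[i] & ~eem.mask[i]
        if not np.any(row_exc):
            continue
        if good.sum() < 2:
            logger.warning(
                "sample %s: excitation row %.0f nm fully excised; "
                "masking instead of interpolating", eem.sample_id, eem.ex[i])
            out.mask[i] |= row_exc
            continue
        out.intensity[i, row_exc] = np.interp(
            eem.em[row_exc], eem.em[good], eem.intensity[i, good])
    out.mask = out.mask | below
    return out


def raman_area(blank: EEMSpectrum) -> float:
    """Integrated water Raman peak of a blank at Ex 350 nm, Em 371-428 nm."""
    return blank.emission_band_area(RAMAN_EX_NM, RAMAN_EM_LO_NM,
                                    RAMAN_EM_HI_NM)


def raman_normalize(eem: EEMSpectrum,
                    blank: EEMSpectrum) -> tuple[EEMSpectrum, float]:
    """Convert an EEM to Raman units (R.U.).

    Divides all intensities by the trapezoidal area under the blank's
    Raman scatter peak at excitation 350 nm over emission 371-428 nm.
    Returns the normalised EEM and the Raman area used.
    """
    area = raman_area(blank)
    if area <= 0:
        raise EEMError(f"invalid blank: Raman area {area:g} <= 0")
    out = eem.copy()
    out.intensity = eem.intensity / area
    out.units = "raman_unit"
    return out, area


def preprocess(sample: EEMSpectrum, blank: EEMSpectrum,
               absorbance: AbsorbanceSpectrum | None = None,
               w1: float = 10.0, w2: float = 10.0,
               raman_halfwidth: float = 15.0,
               fill: str = "mask") -> tuple[EEMSpectrum, float]:
    """Full preprocessing chain: blank subtraction, optional inner-filter
    correction, Raman normalisation, then scatter excision.

    Returns the processed EEM (Raman units) and the Raman area.
    """
    out = subtract_blank(sample, blank)
    if absorbance is not None:
        out = inner_filter_correct(out, absorbance)
    out, area = raman_normalize(out, blank)
    out = remove_scatter(out, w1=w1, w2=w2, raman_halfwidth=raman_halfwidth,
                         fill=fill)
    return out, area
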