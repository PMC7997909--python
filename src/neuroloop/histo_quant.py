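"""Histology quantification.

Two image-derived measures:

* **Spared tissue at the lesion epicenter** — images are divided into
  square regions of interest, binarized at a fixed intensity threshold
  held constant across sections, and the spared percentage is 100x the
  positive-pixel count of the epicenter section over the mean positive
  count of the adjacent intact sections.
* **c-Fos density vs distance from the electrode tip** — spot
  coordinates are converted to radial distance d = sqrt(dX^2 + dY^2),
  counted in half-open 250 um bins (k*250, (k+1)*250]; the bin closest to
  the electrode is excluded (tissue damage) and each animal's profile is
  scaled to [0, 1] by its maximum count (the scale floor is the natural
  zero of a count).  A pooled ordinary-least-squares slope of normalized
  density on distance is provided together with the long-format table a
  mixed-effects fit would consume; the mixed model itself is out of
  scope here.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclasses.dataclass
class SectionImage:
    pixels: np.ndarray              # 2-D intensity grid
    um_per_px: float = 1.0
    role: str = "epicenter"         # epicenter | rostral_intact | caudal_intact

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("section image must be 2-D")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")


@dataclasses.dataclass
class SpotSet:
    """Detected c-Fos+ spot coordinates plus the electrode tip reference."""

    xy_um: np.ndarray               # (N, 2)
    tip_um: tuple[float, float]
    animal_id: str = "animal"

    def __post_init__(self) -> None:
        self.xy_um = np.atleast_2d(np.asarray(self.xy_um, dtype=float))
        if self.xy_um.shape[1] != 2:
            raise ValueError("xy_um must be (N, 2)")
        if not np.all(np.isfinite(self.xy_um)) or not np.all(
                np.isfinite(self.tip_um)):
            raise ValueError("coordinates must be finite")

    @property
    def distances_um(self) -> np.ndarray:
        d = self.xy_um - np.asarray(self.tip_um)[None, :]
        return np.hypot(d[:, 0], d[:, 1])


def load_section(path: str, um_per_px: float = 1.0,
                 role: str = "epicenter") -> SectionImage:
    """Read a TIFF/PNG section (first channel if multichannel)."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:
        img = img[..., 0]
    return SectionImage(img, um_per_px, role)


def roi_positive_counts(section: SectionImage, intensity_threshold: float,
                        roi_px: int = 64) -> pd.DataFrame:
    """Positive-pixel counts per square ROI (bookkeeping / provenance)."""
    binary = section.pixels >= intensity_threshold
    rows = []
    h, w = binary.shape
    for i in range(0, h, roi_px):
        for j in range(0, w, roi_px):
            rows.append({"row": i // roi_px, "col": j // roi_px,
                         "positive_px": int(binary[i:i + roi_px,
                                                   j:j + roi_px].sum())})
    return pd.DataFrame(rows)


def spared_tissue_percent(epicenter: SectionImage,
                          intacts: list[SectionImage],
                          intensity_threshold: float,
                          roi_px: int | None = None) -> float:
    """Spared-tissue percentage at the lesion epicenter.

    100 x positive-pixel count(epicenter) / mean positive count(intact
    sections), all binarized at the same fixed threshold.  Invariant to
    translation and to any monotone intensity rescaling that preserves
    the threshold's level set.
    """
    if not intacts:
        raise ValueError("need at least one intact section")
    if any(s.um_per_px != epicenter.um_per_px for s in intacts):
        raise ValueError("sections must share the same scale")

    def _count(section: SectionImage) -> float:
        if roi_px is not None:
            return float(roi_positive_counts(section, intensity_threshold,
                                             roi_px)["positive_px"].sum())
        return float((section.pixels >= intensity_threshold).sum())

    intact_counts = [_count(s) for s in intacts]
    denom = float(np.mean(intact_counts))
    if denom == 0:
        raise ValueError("no positive pixels in any intact section")
    return 100.0 * _count(epicenter) / denom


def cfos_distance_profile(spots: SpotSet, bin_um: float = 250.0,
                          drop_first_bin: bool = True,
                          max_distance_um: float | None = None) -> pd.DataFrame:
    """Binned, per-animal-normalized c-Fos density vs distance from the tip.

    Counts per half-open bin (k*bin, (k+1)*bin], k=0 excluded by default;
    normalization divides by the profile maximum (floor fixed at 0), so
    doubling all counts leaves the profile unchanged.  Columns:
    ``animal``, ``bin_index``, ``bin_center_um``, ``count``,
    ``density_norm``.  Empty beyond the excluded bin -> empty frame with
    a warning.
    """
    d = spots.distances_um
    if d.size == 0:
        raise ValueError("need at least one spot")
    if max_distance_um is None:
        max_distance_um = float(d.max())
    n_bins = max(int(np.ceil(max_distance_um / bin_um)), 1)
    # half-open (k*bin, (k+1)*bin]; zero distance goes to the first bin
    idx = np.clip(np.ceil(d / bin_um).astype(int) - 1, 0, None)
    idx = idx[idx < n_bins]
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    k0 = 1 if drop_first_bin else 0
    kept = counts[k0:]
    if kept.size == 0 or kept.sum() == 0:
        warnings.warn("no spots beyond the excluded bin; empty profile")
        return pd.DataFrame(columns=["animal", "bin_index", "bin_center_um",
                                     "count", "density_norm"])
    norm = kept / kept.max()
    k = np.arange(k0, n_bins)
    return pd.DataFrame({
        "animal": spots.animal_id,
        "bin_index": k,
        "bin_center_um": (k + 0.5) * bin_um,
        "count": kept,
        "density_norm": norm,
    })


def excluded_bin_count(spots: SpotSet, bin_um: float = 250.0) -> int:
    """Number of spots in the excluded closest bin (0, bin_um]."""
    return int((spots.distances_um <= bin_um).sum())


def density_distance_regression(profiles: list[pd.DataFrame] | pd.DataFrame
                                ) -> dict:
    """Pooled OLS slope of normalized density on distance, plus the table.

    ``profiles`` are per-animal frames from :func:`cfos_distance_profile`
    (>= 2 retained bins per animal).  The long-format table (animal,
    distance, density) is what a mixed-effects fit with a per-animal
    intercept would consume.
    """
    table = pd.concat(profiles, ignore_index=True) if isinstance(
        profiles, list) else profiles.copy()
    if table.empty:
        raise ValueError("no profiles to regress")
    per_animal = table.groupby("animal").size()
    if (per_animal < 2).any():
        raise ValueError("each animal needs >= 2 distance bins")
    X = sm.add_constant(table["bin_center_um"].to_numpy())
    fit = sm.OLS(table["density_norm"].to_numpy(), X).fit()
    return {
        "table": table[["animal", "bin_center_um", "density_norm"]],
        "slope_per_um": float(fit.params[1]),
        "slope_se": float(fit.bse[1]),
        "intercept": float(fit.params[0]),
        "n_rows": int(len(table)),
    }
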