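"""Comparative quantification of cross-links via XIC area ratios.

The untreated enzyme is cross-linked with light (d0) BS3 and the
dephosphorylated enzyme with heavy (d4) BS3; after pooling, each validated
link is quantified as the ratio of the areas of the extracted ion
chromatograms of its light and heavy precursors.  A ratio > 1 means the
cross-link is reduced in the dephosphorylated form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import Chromatogram

__all__ = [
    "Xic",
    "QuantConfig",
    "QuantLink",
    "QuantResult",
    "extract_xic",
    "integrate",
    "classify_fold_change",
    "compare",
    "quant_table",
]


@dataclass
class Xic:
    """Extracted ion chromatogram for one target m/z window."""

    mz: float
    tol_ppm: float
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.rt) > 1 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("rt must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    def __len__(self) -> int:
        return len(self.rt)


@dataclass
class QuantConfig:
    tol_ppm: float = 10.0
    rt_halfwidth: float = 30.0            # seconds around the link's rt
    #: fold-change bin edges; [1, 2) unchanged, [2, 5), [5, 10), >= 10
    bins: tuple[float, float, float] = (2.0, 5.0, 10.0)
    rt_shift: float = 0.0                 # optional heavy-run rt correction


@dataclass
class QuantLink:
    """Quantification coordinates of one validated link."""

    key: tuple
    mz_light: float
    mz_heavy: float
    z: int
    rt: float
    is_interprotein: bool = True


@dataclass
class QuantResult:
    key: tuple
    light_area: float
    heavy_area: float
    ratio: float                           # light/heavy = untreated/dephos
    fold_change: float
    fold_class: str                        # unchanged | 2-5 | 5-10 | >10
    direction: str                         # none | reduced | increased
    flagged: bool = False                  # True when an area was zero
    is_interprotein: bool = True


def extract_xic(
    run: Sequence,
    mz: float,
    tol_ppm: float = 10.0,
    rt_window: tuple[float, float] | None = None,
) -> Xic:
    """Sum MS1 feature intensities within mz +/- tol at each retention time.

    ``run`` is a sequence of features with mz/rt/intensity attributes.  The
    window is clipped to the run's rt bounds; a target absent from the run
    yields an all-zero trace on the run's rt grid.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    if not len(run):
        raise ValueError("empty run")
    rts = np.array(sorted({f.rt for f in run}))
    if rt_window is not None:
        lo = max(rt_window[0], rts[0])
        hi = min(rt_window[1], rts[-1])
        rts = rts[(rts >= lo) & (rts <= hi)]
    tol = mz * tol_ppm * 1e-6
    acc = {rt: 0.0 for rt in rts}
    for f in run:
        if abs(f.mz - mz) <= tol and f.rt in acc:
            acc[f.rt] += f.intensity
    return Xic(mz, tol_ppm, rts, np.array([acc[rt] for rt in rts]))


def integrate(xic) -> float:
    """Trapezoidal area of an XIC (or any rt/intensity trace)."""
    if len(xic.rt) < 2:
        raise ValueError("need at least 2 points to integrate")
    return float(np.trapezoid(xic.intensity, xic.rt))


def classify_fold_change(
    ratio: float, bins: tuple[float, float, float] = (2.0, 5.0, 10.0)
) -> tuple[float, str, str]:
    """Map a light/heavy ratio to (fold change, class, direction).

    The class is computed on the symmetric fold change max(r, 1/r) with
    half-open bins [b0, b1), [b1, b2), [b2, inf); a boundary value falls in
    the higher bin.  Direction is 'reduced' when the heavy (dephosphorylated)
    signal is lower.
    """
    b0, b1, b2 = bins
    if math.isinf(ratio):
        fold = math.inf
    else:
        fold = ratio if ratio >= 1 else 1.0 / ratio if ratio > 0 else math.inf
    if fold < b0:
        klass = "unchanged"
    elif fold < b1:
        klass = f"{b0:g}-{b1:g}"
    elif fold < b2:
        klass = f"{b1:g}-{b2:g}"
    else:
        klass = f">{b2:g}"
    if klass == "unchanged":
        direction = "none"
    else:
        direction = "reduced" if ratio >= 1 else "increased"
    return fold, klass, direction


def compare(
    link: QuantLink,
    run_light: Sequence,
    run_heavy: Sequence,
    config: QuantConfig | None = None,
) -> QuantResult:
    """Quantify one link: area(d0, untreated) / area(d4, dephosphorylated).

    ``run_light`` and ``run_heavy`` may be the same pooled run; the two
    XICs are then separated purely by the isotope m/z offset.  A zero heavy
    area yields an infinite ratio, class '>10', flagged.
    """
    config = config or QuantConfig()
    window = (link.rt - config.rt_halfwidth, link.rt + config.rt_halfwidth)
    shifted = (window[0] + config.rt_shift, window[1] + config.rt_shift)
    light = extract_xic(run_light, link.mz_light, config.tol_ppm, window)
    heavy = extract_xic(run_heavy, link.mz_heavy, config.tol_ppm, shifted)
    a_light = integrate(light)
    a_heavy = integrate(heavy)
    flagged = a_heavy == 0 or a_light == 0
    ratio = a_light / a_heavy if a_heavy > 0 else math.inf
    fold, klass, direction = classify_fold_change(ratio, config.bins)
    return QuantResult(
        key=link.key,
        light_area=a_light,
        heavy_area=a_heavy,
        ratio=ratio,
        fold_change=fold,
        fold_class=klass,
        direction=direction,
        flagged=flagged,
        is_interprotein=link.is_interprotein,
    )


def quant_table(
    links: Sequence[QuantLink],
    run_light: Sequence,
    run_heavy: Sequence,
    config: QuantConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """One QuantResult per link plus per-class and intra/inter summaries."""
    if not links:
        raise ValueError("at least one validated link required")
    results = [compare(l, run_light, run_heavy, config) for l in links]
    df = pd.DataFrame(
        {
            "link": [str(r.key) for r in results],
            "light_area": [r.light_area for r in results],
            "heavy_area": [r.heavy_area for r in results],
            "ratio": [r.ratio for r in results],
            "fold_class": [r.fold_class for r in results],
            "direction": [r.direction for r in results],
            "interprotein": [r.is_interprotein for r in results],
            "flagged": [r.flagged for r in results],
        }
    )
    summary = {
        "n_links": len(results),
        "by_class": df["fold_class"].value_counts().to_dict(),
        "n_changed": int((df["fold_class"] != "unchanged").sum()),
        "n_unchanged": int((df["fold_class"] == "unchanged").sum()),
        "n_interprotein": int(df["interprotein"].sum()),
        "n_intraprotein": int((~df["interprotein"]).sum()),
    }
    return df, summary
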