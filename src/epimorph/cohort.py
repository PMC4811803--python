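"""Multi-animal registration, ensemble averaging and significance.

Movies from different animals are registered in space using stereotyped
landmarks (sensory-bristle positions in the fly notum) and in time using
the stereotyped peak of the tissue rotation rate.  Registered per-box
fields are then ensemble-averaged with their weights, the biological
variability is measured as a weighted unbiased standard deviation, and a
per-box significance criterion compares the mean deviator amplitude with
the variability.  Wild-type and mutant cohorts on a common archetype grid
are compared by per-box tensor differences and their projection onto the
wild-type morphogenesis axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tensors import SymTensor2, project_component


# ---------------------------------------------------------------------------
# space registration
# ---------------------------------------------------------------------------

@dataclass
class SpaceRegistration:
    archetype: np.ndarray        # (P, 2) mean landmark positions
    scale: np.ndarray            # (A, 2) per-animal (alpha_x, alpha_y)
    dispersion_before: float     # rms landmark distance to archetype
    dispersion_after: float


def space_register(landmarks: np.ndarray, mirror: np.ndarray | None = None
                   ) -> SpaceRegistration:
    """Archetype landmarks and per-animal axis scale factors.

    ``landmarks`` is an (A, P, 2) array of P shared landmark positions for
    A animals, already translated to a common origin (the landmark
    barycentre).  ``mirror`` optionally flags animals whose y axis must be
    flipped (left hemi-tissues) before registration.  The archetype
    landmark is the across-animal barycentre; each animal's scale factor
    along an axis is alpha = sum(x * xbar) / sum(x^2), the least-squares
    multiplier minimizing its landmark dispersion from the archetype.
    A single animal gets alpha = 1.
    """
    lm = np.array(landmarks, dtype=float)
    if lm.ndim != 3 or lm.shape[2] != 2:
        raise ValueError("landmarks must be (animals, points, 2)")
    if mirror is not None:
        lm[np.asarray(mirror, bool), :, 1] *= -1.0
    n_animals = lm.shape[0]
    arche = lm.mean(axis=0)
    if n_animals == 1:
        return SpaceRegistration(arche, np.ones((1, 2)), 0.0, 0.0)
    scale = np.empty((n_animals, 2))
    for a in range(n_animals):
        for ax in range(2):
            x = lm[a, :, ax]
            denom = np.sum(x * x)
            scale[a, ax] = np.sum(x * arche[:, ax]) / denom if denom > 0 else 1.0
    before = float(np.sqrt(np.mean((lm - arche) ** 2)))
    rescaled = lm * scale[:, None, :]
    after = float(np.sqrt(np.mean((rescaled - rescaled.mean(axis=0)) ** 2)))
    return SpaceRegistration(arche, scale, before, after)


def mirror_tensor_components(df: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Flip a hemi-tissue about the midline: n -> -n and Qxy -> -Qxy."""
    out = df.copy()
    if "n" in out:
        out["n"] = -out["n"]
    cols = columns if columns is not None else [
        c for c in out.columns if c.endswith("_xy")
    ]
    for c in cols:
        out[c] = -out[c]
    if "omega" in out:
        out["omega"] = -out["omega"]
    return out


# ---------------------------------------------------------------------------
# time registration
# ---------------------------------------------------------------------------

def _smooth(y: np.ndarray, half: int) -> np.ndarray:
    if half <= 0:
        return y.astype(float)
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    return np.convolve(np.pad(y.astype(float), half, mode="edge"), kernel,
                       mode="valid")


def reference_time(series: np.ndarray, smooth_half: int = 0,
                   noise_floor: float = 0.0) -> float | None:
    """Frame (fractional) where a rotation-rate series first reaches 3/4 of
    its peak value on the rising flank.

    The maximum of the (optionally smoothed) series defines the peak; the
    3/4 crossing is located by linear interpolation between frames.  The
    steep ascent localizes better than the flat peak itself.  Returns None
    when no peak rises above ``noise_floor`` or the series is monotone up
    to its last point (no detectable peak).
    """
    y = _smooth(np.asarray(series, dtype=float), smooth_half)
    imax = int(np.argmax(y))
    peak = y[imax]
    if peak <= noise_floor or imax == 0 or imax == len(y) - 1:
        return None
    thresh = 0.75 * peak
    for i in range(imax, 0, -1):
        if y[i - 1] < thresh <= y[i]:
            frac = (thresh - y[i - 1]) / (y[i] - y[i - 1])
            return (i - 1) + float(frac)
    return None if y[0] >= thresh and imax == 0 else 0.0


def time_register(series_per_animal, smooth_half: int = 0,
                  noise_floor: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-animal time offsets (frames) aligning rotation-rate peaks.

    Offsets are reported relative to the cohort mean reference time, so
    applying them synchronizes the 3/4-ascent crossings.  Animals without
    a detectable peak are flagged (offset 0, flag False).
    """
    refs, flags = [], []
    for s in series_per_animal:
        r = reference_time(s, smooth_half=smooth_half, noise_floor=noise_floor)
        flags.append(r is not None)
        refs.append(r if r is not None else np.nan)
    refs = np.asarray(refs, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    mean_ref = np.nanmean(refs) if flags.any() else 0.0
    offsets = np.where(flags, refs - mean_ref, 0.0)
    return offsets, flags


def dilate_time(rates: pd.DataFrame, factor: float = 0.9,
                columns=None) -> pd.DataFrame:
    """Correct a cohort acquired at a faster developmental rate.

    Time intervals are divided by ``factor`` (default 0.9, the empirical
    acceleration at 29 C), hence all rate columns are multiplied by it.
    """
    out = rates.copy()
    cols = columns if columns is not None else [
        c for c in out.columns
        if any(c.startswith(f"{s}_") for s in
               ("G", "S", "D", "R", "A", "N", "C", "J")) or c == "omega"
    ]
    for c in cols:
        out[c] = out[c] * factor
    return out


# ---------------------------------------------------------------------------
# ensemble statistics
# ---------------------------------------------------------------------------

def ensemble_average(values: np.ndarray, weights: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Weighted ensemble mean over animals (axis 0) and the mean weight.

    Boxes where all weights vanish yield NaN.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    wsum = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(wsum > 0, (w * v).sum(axis=0) / wsum, np.nan)
    return mean, w.mean(axis=0)


def weighted_std(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Unbiased weighted standard deviation across animals (axis 0).

    Uses the prefactor sum(W) / (sum(W)^2 - sum(W^2)), which reduces to
    1/(Ns - 1) when all weights are 1.  Boxes with effective sample size
    <= 1 (prefactor undefined) yield NaN.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    wsum = w.sum(axis=0)
    w2sum = (w**2).sum(axis=0)
    denom = wsum**2 - w2sum
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(wsum > 0, (w * v).sum(axis=0) / wsum, np.nan)
        var = np.where(
            denom > 0,
            wsum / denom * (w * (v - mean) ** 2).sum(axis=0),
            np.nan,
        )
    return np.sqrt(var)


def significance_mask(
    mean_xx, mean_xy, mean_yy, std_xx_minus_yy, std_xy
) -> np.ndarray:
    """Per-box deviator significance: |mean CE| >= |variability CE|.

    A measurement is significant where
    sqrt((Qxx-Qyy)^2 + 4 Qxy^2) >= sqrt(d(Qxx-Qyy)^2 + 4 dQxy^2); when
    bar directions vary strongly between animals the mean deviator shrinks
    and the box becomes non-significant.
    """
    lhs = np.sqrt((np.asarray(mean_xx) - np.asarray(mean_yy)) ** 2
                  + 4.0 * np.asarray(mean_xy) ** 2)
    rhs = np.sqrt(np.asarray(std_xx_minus_yy) ** 2
                  + 4.0 * np.asarray(std_xy) ** 2)
    return lhs >= rhs


@dataclass
class EnsembleField:
    """Ensemble statistics of one tensor quantity on the archetype grid."""

    table: pd.DataFrame  # m, n, [frame,] mean_xx/xy/yy, std_*, Wbar, significant


def ensemble_field(
    per_animal: list[pd.DataFrame],
    symbol: str,
    weight_col: str = "Wa",
    keys: tuple[str, ...] = ("m", "n", "frame"),
) -> EnsembleField:
    """Align per-animal rate tables on (m, n[, frame]) and compute the
    ensemble mean, weighted standard deviation and significance of one
    tensor quantity ``symbol`` (e.g. "G")."""
    cols = [f"{symbol}_xx", f"{symbol}_xy", f"{symbol}_yy"]
    keys = [k for k in keys if all(k in df.columns for df in per_animal)]
    frames = []
    for a, df in enumerate(per_animal):
        sub = df[list(keys) + cols + [weight_col]].copy()
        sub["animal"] = a
        frames.append(sub)
    allf = pd.concat(frames, ignore_index=True)
    rows = []
    for key_vals, grp in allf.groupby(list(keys), sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        w = grp[weight_col].to_numpy(float)
        vals = grp[cols].to_numpy(float)
        mean, wbar = ensemble_average(vals, np.repeat(w[:, None], 3, axis=1))
        dev_comp = np.stack([vals[:, 0] - vals[:, 2], vals[:, 1]], axis=1)
        stds = weighted_std(dev_comp, np.repeat(w[:, None], 2, axis=1))
        sig = bool(
            significance_mask(mean[0], mean[1], mean[2], stds[0], stds[1])
        ) if np.isfinite(stds).all() else False
        row = dict(zip(keys, key_vals))
        row.update({
            f"{symbol}_xx": mean[0], f"{symbol}_xy": mean[1],
            f"{symbol}_yy": mean[2],
            f"d{symbol}_xx_minus_yy": stds[0], f"d{symbol}_xy": stds[1],
            "Wbar": float(wbar[0]), "significant": sig,
        })
        rows.append(row)
    return EnsembleField(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# genotype comparison
# ---------------------------------------------------------------------------

def condition_difference(
    p_mutant: pd.DataFrame,
    p_wt: pd.DataFrame,
    g_wt: pd.DataFrame,
    symbol: str,
    g_symbol: str = "G",
    keys: tuple[str, ...] = ("m", "n", "frame"),
) -> pd.DataFrame:
    """Per-box mutant-minus-wild-type difference and its component along
    the wild-type morphogenesis axis.

    Delta P = P_mutant - P_wt is the part of the mutant's process P added
    by the condition; Delta P// projects it on the wild-type tissue CE
    direction.  Tables must live on the same archetype grid.
    """
    keys = [k for k in keys
            if k in p_mutant.columns and k in p_wt.columns and k in g_wt.columns]
    cols = [f"{symbol}_{c}" for c in ("xx", "xy", "yy")]
    gcols = [f"{g_symbol}_{c}" for c in ("xx", "xy", "yy")]
    a = p_mutant[keys + cols].set_index(keys)
    b = p_wt[keys + cols].set_index(keys)
    g = g_wt[keys + gcols].set_index(keys)
    if not a.index.equals(b.index):
        a, b = a.align(b, join="inner")
        if len(a) == 0:
            raise ValueError("mutant and wild-type grids do not overlap")
    if set(a.index) != set(g.index):
        g = g.reindex(a.index)
        if g.isna().any().any():
            raise ValueError("wild-type G grid does not cover the comparison grid")
    diff = a[cols].to_numpy(float) - b[cols].to_numpy(float)
    gv = g[gcols].to_numpy(float)
    par = np.array([
        project_component(SymTensor2(*d), SymTensor2(*gg))
        for d, gg in zip(diff, gv)
    ])
    out = a.reset_index()[keys]
    out[f"delta{symbol}_xx"] = diff[:, 0]
    out[f"delta{symbol}_xy"] = diff[:, 1]
    out[f"delta{symbol}_yy"] = diff[:, 2]
    out[f"delta{symbol}_par"] = par
    return out
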