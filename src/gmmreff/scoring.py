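"""Global and local map–model quality-of-fit scores.

* ``ccc`` — zero-mean Pearson correlation between two maps over a voxel
  support (the convergence score of the refinement).
* ``fsc`` — Fourier shell correlation curve between two maps.
* ``loqfit`` — per-residue local fit: the resolution (Å) at which the FSC
  between the experimental map and the model-simulated map, both under a
  soft spherical mask centred on the residue anchor atom, first crosses
  0.5.  Lower is better; values are censored at the Nyquist limit.
* ``smocf`` — per-residue Manders overlap coefficient between simulated
  and experimental density over a sliding residue window.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .forward import GMMState, simulate_map, support_mask
from .grid import DensityMap
from .models import AtomicModel

log = logging.getLogger(__name__)

__all__ = ["LocalScoreTrack", "ccc", "fsc", "loqfit", "smocf"]


def ccc(
    map_a: DensityMap | np.ndarray,
    map_b: DensityMap | np.ndarray,
    support: np.ndarray | None = None,
) -> float:
    """Zero-mean Pearson correlation over the supported voxels.

    Raises ``ValueError`` if either map has zero variance on the support.
    """
    a = map_a.values if isinstance(map_a, DensityMap) else np.asarray(map_a)
    b = map_b.values if isinstance(map_b, DensityMap) else np.asarray(map_b)
    if a.shape != b.shape:
        raise ValueError("maps must share a grid")
    if support is not None:
        a = a[support]
        b = b[support]
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        raise ValueError("CCC undefined: zero variance on the support")
    return float(np.dot(a, b) / denom)


def _pad_to_cube(values: np.ndarray) -> np.ndarray:
    n = max(values.shape)
    if values.shape == (n, n, n):
        return values
    out = np.zeros((n, n, n), dtype=values.dtype)
    out[: values.shape[0], : values.shape[1], : values.shape[2]] = values
    return out


def fsc(map_a: DensityMap, map_b: DensityMap) -> pd.DataFrame:
    """Fourier shell correlation between two maps on the same grid.

    Non-cubic grids are zero-padded to a cube.  Shell width is one
    reciprocal voxel; empty shells are skipped.  Returns a DataFrame with
    columns ``frequency`` (1/Å), ``correlation`` and ``n_voxels``.
    """
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share a grid")
    if not np.allclose(map_a.voxel_size, map_a.voxel_size[0], rtol=1e-6):
        raise ValueError("FSC requires an isotropic voxel")
    voxel = float(map_a.voxel_size[0])
    a = _pad_to_cube(map_a.values)
    b = _pad_to_cube(map_b.values)
    n = a.shape[0]
    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    freq = np.fft.fftfreq(n, d=voxel)
    k2 = (
        freq[:, None, None] ** 2 + freq[None, :, None] ** 2 + freq[None, None, :] ** 2
    )
    df = 1.0 / (n * voxel)
    shell = np.rint(np.sqrt(k2) / df).astype(int)
    nshell = n // 2 + 1
    valid = shell < nshell
    s = shell[valid]
    num = np.bincount(s, weights=(fa * np.conj(fb)).real[valid], minlength=nshell)
    pa = np.bincount(s, weights=np.abs(fa[valid]) ** 2, minlength=nshell)
    pb = np.bincount(s, weights=np.abs(fb[valid]) ** 2, minlength=nshell)
    count = np.bincount(s, minlength=nshell)
    keep = (count > 0) & (pa > 0) & (pb > 0)
    corr = np.full(nshell, np.nan)
    corr[keep] = num[keep] / np.sqrt(pa[keep] * pb[keep])
    out = pd.DataFrame(
        {
            "frequency": np.arange(nshell) * df,
            "correlation": corr,
            "n_voxels": count,
        }
    )
    return out[keep].reset_index(drop=True)


@dataclasses.dataclass
class LocalScoreTrack:
    """Per-residue local score values.

    ``entries`` has one row per scored residue with columns ``chain_id``,
    ``residue_index``, ``value`` and (for LoQFit) ``censored``.
    """

    score_name: str
    entries: pd.DataFrame

    def __post_init__(self) -> None:
        if self.score_name == "SMOCf":
            v = self.entries["value"].to_numpy()
            if len(v) and (v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9):
                raise ValueError("SMOCf values must lie in [-1, 1]")

    def values(self) -> np.ndarray:
        return self.entries["value"].to_numpy()

    def to_dataframe(self) -> pd.DataFrame:
        return self.entries.copy()

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)

    def plot(self, ax=None):  # pragma: no cover - convenience plotting
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for chain, sub in self.entries.groupby("chain_id"):
            ax.plot(sub["residue_index"], sub["value"], label=f"chain {chain}")
        ax.set_xlabel("residue")
        unit = " (Å)" if self.score_name == "LoQFit" else ""
        ax.set_ylabel(f"{self.score_name}{unit}")
        ax.legend()
        return ax


def _soft_spherical_mask(
    grid: DensityMap, center: np.ndarray, radius: float, edge_voxels: float = 3.0
) -> np.ndarray:
    """Raised-cosine soft mask: 1 inside ``radius``, cosine falloff over
    ``edge_voxels`` voxels, 0 beyond."""
    edge = edge_voxels * float(np.max(grid.voxel_size))
    cx = grid.axis_coords(0) - center[0]
    cy = grid.axis_coords(1) - center[1]
    cz = grid.axis_coords(2) - center[2]
    r = np.sqrt(
        cx[:, None, None] ** 2 + cy[None, :, None] ** 2 + cz[None, None, :] ** 2
    )
    mask = np.zeros(grid.shape)
    mask[r <= radius] = 1.0
    rim = (r > radius) & (r < radius + edge)
    mask[rim] = 0.5 * (1.0 + np.cos(np.pi * (r[rim] - radius) / edge))
    return mask


def _fsc_crossing_resolution(curve: pd.DataFrame, threshold: float = 0.5) -> float | None:
    """Resolution (Å) of the first low→high frequency crossing of the
    threshold, linearly interpolated in frequency; None if never crossed."""
    f = curve["frequency"].to_numpy()
    c = curve["correlation"].to_numpy()
    # skip the DC shell for crossing detection but use it as left anchor
    for i in range(1, len(f)):
        if c[i] < threshold:
            f0, c0 = (f[i - 1], c[i - 1]) if i >= 1 else (0.0, 1.0)
            if c0 <= threshold:  # started below threshold already
                return 1.0 / f[i] if f[i] > 0 else None
            fx = f0 + (c0 - threshold) / (c0 - c[i]) * (f[i] - f0)
            return 1.0 / fx if fx > 0 else None
    return None


def loqfit(
    model: AtomicModel,
    exp_map: DensityMap,
    global_resolution: float | None = None,
    threshold: float = 0.5,
    cutoff_sigma: float = 4.0,
) -> LocalScoreTrack:
    """Per-residue local FSC-0.5 resolution under a soft spherical mask.

    The mask diameter is five times the global resolution, centred on each
    residue's Cα (C1′ for nucleotides).  The simulated map uses the
    model's own per-atom widths.  Residues whose masked FSC never drops
    below the threshold are censored at the Nyquist resolution
    ``2 × max(voxel_size)`` (best attainable score).
    """
    resolution = (
        float(global_resolution)
        if global_resolution is not None
        else exp_map.global_resolution
    )
    if resolution is None:
        raise ValueError("global_resolution is required for LoQFit")
    nyquist = 2.0 * float(np.max(exp_map.voxel_size))
    radius = 2.5 * resolution  # mask diameter = 5 x resolution
    sim = simulate_map(GMMState(model, 0.0, cutoff_sigma), exp_map)
    anchors = model.anchor_indices()
    rows = []
    for (chain, resi), ai in anchors.items():
        mask = _soft_spherical_mask(exp_map, model.positions[ai], radius)
        curve = fsc(exp_map.like(exp_map.values * mask), exp_map.like(sim.values * mask))
        value = _fsc_crossing_resolution(curve, threshold)
        censored = value is None or value < nyquist
        if censored:
            value = nyquist
        rows.append(
            {
                "chain_id": chain,
                "residue_index": resi,
                "value": float(value),
                "censored": censored,
            }
        )
    skipped = len(model.residue_groups()) - len(anchors)
    if skipped:
        log.info("loqfit: %d residues without an anchor atom skipped", skipped)
    return LocalScoreTrack("LoQFit", pd.DataFrame(rows))


def manders_overlap(a: np.ndarray, b: np.ndarray) -> float:
    """Manders overlap coefficient Σab / sqrt(Σa²·Σb²) (0 if degenerate)."""
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        return 0.0
    return float(np.sum(a * b) / denom)


def smocf(
    model: AtomicModel,
    exp_map: DensityMap,
    window_residues: int = 9,
    cutoff_sigma: float = 4.0,
) -> LocalScoreTrack:
    """Sliding-window Manders overlap between simulated and experimental
    density around each residue.

    For each residue, the window spans ``±(window_residues−1)/2``
    neighbouring residues on the same chain (truncated at termini); the
    scored region is the voxel set within ``cutoff_sigma·B`` of the
    window's atoms.
    """
    if window_residues < 1 or window_residues % 2 == 0:
        raise ValueError("window_residues must be odd and >= 1")
    half = (window_residues - 1) // 2
    sim = simulate_map(GMMState(model, 0.0, cutoff_sigma), exp_map)
    groups = model.residue_groups()
    by_chain: dict[str, list[tuple[int, np.ndarray]]] = {}
    for (chain, resi), idx in groups.items():
        by_chain.setdefault(chain, []).append((resi, idx))
    rows = []
    for chain, residues in by_chain.items():
        residues.sort(key=lambda t: t[0])
        for j, (resi, _) in enumerate(residues):
            window = residues[max(0, j - half) : j + half + 1]
            atom_idx = np.concatenate([idx for _, idx in window])
            sub = model.subset(atom_idx)
            region = support_mask(GMMState(sub, 0.0, cutoff_sigma), exp_map)
            if not region.any():
                log.info("smocf: residue %s/%d has no supported voxels", chain, resi)
                continue
            rows.append(
                {
                    "chain_id": chain,
                    "residue_index": resi,
                    "value": manders_overlap(
                        sim.values[region], exp_map.values[region]
                    ),
                }
            )
    return LocalScoreTrack("SMOCf", pd.DataFrame(rows))
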