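"""Match-length distributions (MLDs) and power-law exponent estimation.

The MLD m_s(r) of a genus set s is the number of maximal exact matches of
length r, per bp of bin width and per genome comparison.  Lengths are
log-binned on a geometric grid with ``bins_per_decade`` points per decade,
with edges at (r_min - 0.5) * 10^(k / bins_per_decade); the half-integer
offset reflects that match lengths are integers.  Bin centers are geometric
means of adjacent edges.

The tail exponent alpha of an MLD is estimated by the method of moments for
a continuous Pareto law with threshold x_m: since mean = x_m (alpha-1)/(alpha-2),
inverting gives alpha = (2 m - 1)/(m - 1) with m = mean / x_m.  By default the
threshold carries the same half-integer continuity correction as the binning
(x_m = r_min - 0.5), which removes the leading discretization bias.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .match_core import InputError

__all__ = [
    "EstimationError",
    "MLD",
    "bin_edges_for",
    "bin_mld",
    "estimate_alpha_moments",
    "estimate_alpha_from_mld",
    "save_mld",
    "load_mld",
]


class EstimationError(ValueError):
    """Raised when an estimator's preconditions fail (degenerate input)."""


@dataclass
class MLD:
    """A log-binned, per-comparison-normalized match-length distribution."""

    genus_set: tuple[str, ...]
    r_min: float
    bin_edges: np.ndarray  # length B + 1, geometric grid
    raw_counts: np.ndarray  # length B, integers
    n_comparisons: int
    density: np.ndarray = field(init=False)  # matches / bp / comparison

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.raw_counts = np.asarray(self.raw_counts, dtype=np.int64)
        if self.n_comparisons < 1:
            raise InputError("n_comparisons must be >= 1")
        if self.bin_edges.size and np.any(np.diff(self.bin_edges) <= 0):
            raise InputError("bin edges must be strictly increasing")
        widths = np.diff(self.bin_edges)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.density = self.raw_counts / widths / self.n_comparisons if widths.size else np.array([])

    @property
    def bin_centers(self) -> np.ndarray:
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def is_empty(self) -> bool:
        return self.raw_counts.size == 0 or int(self.raw_counts.sum()) == 0

    @property
    def populated(self) -> np.ndarray:
        """Boolean mask of bins with at least one match."""
        return self.raw_counts > 0


def bin_edges_for(r_min: float, r_max: float, bins_per_decade: int = 20) -> np.ndarray:
    """Geometric bin edges (r_min - 0.5) * 10^(k/bins_per_decade) covering r_max."""
    start = r_min - 0.5
    if start <= 0:
        raise InputError("r_min must exceed 0.5")
    n = int(np.ceil(np.log10((r_max + 0.5) / start) * bins_per_decade)) + 1
    n = max(n, 1)
    return start * 10 ** (np.arange(n + 1) / bins_per_decade)


def bin_mld(
    lengths: Sequence[int],
    r_min: float,
    n_comparisons: int = 1,
    bins_per_decade: int = 20,
    genus_set: Sequence[str] = (),
) -> MLD:
    """Bin match lengths into a normalized MLD.

    All lengths must be >= r_min; an empty list yields an empty (zero-bin)
    MLD flagged via ``is_empty``.
    """
    lengths = np.asarray(lengths, dtype=float)
    if n_comparisons < 1:
        raise InputError("n_comparisons must be >= 1")
    if lengths.size == 0:
        return MLD(tuple(genus_set), r_min, np.array([]), np.array([]), n_comparisons)
    if np.any(lengths < r_min):
        raise InputError("all lengths must be >= r_min")
    edges = bin_edges_for(r_min, float(lengths.max()), bins_per_decade)
    counts, _ = np.histogram(lengths, bins=edges)
    return MLD(tuple(genus_set), r_min, edges, counts, n_comparisons)


def estimate_alpha_moments(
    lengths: Sequence[int],
    r_min: float,
    continuity_correction: bool = True,
) -> float:
    """Method-of-moments Pareto tail exponent alpha = (2m - 1)/(m - 1).

    ``m`` is the sample mean divided by the threshold; with
    ``continuity_correction`` the threshold is r_min - 0.5 (appropriate for
    integer match lengths truncated at r_min).  Estimates <= 2 are returned
    with a warning: the fitted law would have no finite mean.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        raise EstimationError("no match lengths")
    if np.any(lengths < r_min):
        raise InputError("all lengths must be >= r_min")
    x_m = r_min - 0.5 if continuity_correction else r_min
    m = float(lengths.mean()) / x_m
    if m <= 1:
        raise EstimationError(f"mean/threshold = {m:.4g} <= 1: exponent not estimable")
    alpha = (2 * m - 1) / (m - 1)
    if alpha <= 2:
        warnings.warn(
            f"alpha estimate {alpha:.3g} <= 2: mean of the fitted law is not finite",
            RuntimeWarning,
            stacklevel=2,
        )
    return alpha


def estimate_alpha_from_mld(mld: MLD) -> float:
    """Moments estimator applied to binned data (counts at bin centers)."""
    if mld.is_empty:
        raise EstimationError("empty MLD")
    total = mld.raw_counts.sum()
    mean = float((mld.raw_counts * mld.bin_centers).sum() / total)
    m = mean / (mld.r_min - 0.5)
    if m <= 1:
        raise EstimationError(f"mean/threshold = {m:.4g} <= 1: exponent not estimable")
    return (2 * m - 1) / (m - 1)


# ---------------------------------------------------------------------------
# Serialization: TSV table plus JSON sidecar with the metadata
# ---------------------------------------------------------------------------


def save_mld(mld: MLD, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "bin_center": mld.bin_centers,
            "bin_lo": mld.bin_edges[:-1] if mld.bin_edges.size else [],
            "bin_hi": mld.bin_edges[1:] if mld.bin_edges.size else [],
            "raw_count": mld.raw_counts,
            "density": mld.density,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "genus_set": list(mld.genus_set),
                "r_min": mld.r_min,
                "n_comparisons": mld.n_comparisons,
            }
        )
    )


def load_mld(path: str | Path) -> MLD:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if len(df):
        edges = np.concatenate([df["bin_lo"].to_numpy(), [df["bin_hi"].iloc[-1]]])
        counts = df["raw_count"].to_numpy()
    else:
        edges = np.array([])
        counts = np.array([])
    return MLD(
        tuple(meta["genus_set"]),
        float(meta["r_min"]),
        edges,
        counts,
        int(meta["n_comparisons"]),
    )
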