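"""Community-level functional components: CWM and Rao quadratic entropy.

For a plot with relative covers p_i (Σp_i = 1 over the retained species)
and species trait values x_i:

* **CWM** = Σ p_i x_i — the cover-weighted community mean trait.
* **FD_Rao** = Σ_i Σ_j p_i p_j d_ij — the abundance-weighted expected
  pairwise trait dissimilarity among coexisting species, with d_ij the
  Gower distance |x_i − x_j| / range standardized to [0, 1] over the
  GLOBAL species pool (so values are comparable across plots).

The dominant matrix-forming engineer species (here *Festuca curvifolia*)
occurs everywhere at very high cover and would mask the functional signal
of the accompanying flora; it is excluded before computing either
component, and covers are renormalized over the remaining species.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CommunityMatrix:
    """Plot × species cover with per-plot altitude.

    ``cover`` is indexed by plot_id with one column per species (any
    nonnegative unit — absolute or percentage cover; all downstream
    quantities are invariant to rescaling).
    """

    cover: pd.DataFrame
    altitude_m: pd.Series

    def __post_init__(self) -> None:
        if (self.cover.to_numpy() < 0).any():
            raise InputError("covers must be nonnegative")
        if not self.cover.index.equals(self.altitude_m.index):
            raise InputError("cover matrix and altitude series must share "
                             "the same plot index")

    @classmethod
    def from_wide_frame(cls, frame: pd.DataFrame) -> "CommunityMatrix":
        """Build from a wide table with plot_id, altitude_m, then species."""
        for col in ("plot_id", "altitude_m"):
            if col not in frame.columns:
                raise InputError(f"community matrix missing column {col!r}")
        frame = frame.set_index("plot_id")
        alt = frame["altitude_m"].astype(float)
        cover = frame.drop(columns=["altitude_m"]).astype(float).fillna(0.0)
        return cls(cover, alt)

    def to_wide_frame(self) -> pd.DataFrame:
        out = self.cover.copy()
        out.insert(0, "altitude_m", self.altitude_m)
        return out.reset_index(names="plot_id")

    @property
    def species(self) -> list[str]:
        return list(self.cover.columns)


@dataclass(frozen=True)
class TraitVector:
    """Species-level values for one quantitative trait (°C here)."""

    trait_id: str
    values: pd.Series  # index: species_id; NaN allowed (species dropped)

    @property
    def range(self) -> float:
        """max − min over the species pool carrying the trait."""
        v = self.values.dropna()
        return float(v.max() - v.min()) if len(v) else 0.0


def gower_distance(x_i: float, x_j: float, trait_range: float) -> float:
    """Range-normalized absolute trait difference, clamped to [0, 1]."""
    if trait_range <= 0:
        raise InputError(f"trait range must be positive, got {trait_range}")
    return float(min(1.0, abs(x_i - x_j) / trait_range))


def exclude_engineer(community: CommunityMatrix,
                     species_id: str) -> CommunityMatrix:
    """Drop the engineer species' cover from every plot."""
    if species_id not in community.cover.columns:
        warnings.warn(f"engineer species {species_id!r} not present in the "
                      f"community matrix; nothing excluded", stacklevel=2)
        return community
    cover = community.cover.drop(columns=[species_id])
    emptied = cover.index[cover.sum(axis=1) <= 0]
    if len(emptied):
        logger.warning("plots emptied by engineer exclusion: %s",
                       list(emptied))
    return CommunityMatrix(cover, community.altitude_m)


def _relative_cover(cover: pd.Series, trait: TraitVector) -> tuple[np.ndarray, np.ndarray]:
    """Retain species with positive cover and a trait value; renormalize."""
    vals = trait.values
    keep = [s for s in cover.index
            if cover[s] > 0 and s in vals.index and np.isfinite(vals[s])]
    if not keep:
        return np.array([]), np.array([])
    p = cover[keep].to_numpy(dtype=float)
    return p / p.sum(), vals[keep].to_numpy(dtype=float)


def community_weighted_mean(cover: pd.Series | dict,
                            trait: TraitVector) -> float:
    """Σ p_i x_i with p renormalized over retained species; NaN if none."""
    cover = pd.Series(cover, dtype=float)
    p, x = _relative_cover(cover, trait)
    if p.size == 0:
        return float("nan")
    return float(p @ x)


def rao_fd(cover: pd.Series | dict, trait: TraitVector) -> float:
    """Rao quadratic entropy Σ_i Σ_j p_i p_j d_ij on Gower distances.

    A plot with a single retained species has no pairs and scores 0.
    """
    cover = pd.Series(cover, dtype=float)
    p, x = _relative_cover(cover, trait)
    if p.size == 0:
        return float("nan")
    if p.size == 1:
        return 0.0
    rng = trait.range
    if rng <= 0:
        # all pool species share one value: every pairwise distance is 0
        return 0.0
    d = np.minimum(1.0, np.abs(x[:, None] - x[None, :]) / rng)
    return float(p @ d @ p)


def functional_components_table(community: CommunityMatrix,
                                traits: list[TraitVector],
                                exclude: str | None = None) -> pd.DataFrame:
    """Per-plot CWM and Rao FD for each trait.

    Plots emptied by the engineer exclusion or by missing trait values
    produce NA rows; a trait with no species overlap with the community is
    an input error.
    """
    if not traits:
        raise InputError("no trait vectors supplied")
    if exclude is not None:
        community = exclude_engineer(community, exclude)
    rows = []
    for trait in traits:
        overlap = set(community.cover.columns) & set(trait.values.dropna().index)
        if not overlap:
            raise InputError(f"trait {trait.trait_id!r}: no species overlap "
                             f"with the community matrix")
        for plot_id in community.cover.index:
            cover = community.cover.loc[plot_id]
            cwm = community_weighted_mean(cover, trait)
            fd = rao_fd(cover, trait)
            n_used = int(_relative_cover(cover, trait)[0].size)
            if n_used == 0:
                logger.warning("plot %s: no species with trait %s; NA row",
                               plot_id, trait.trait_id)
            rows.append({
                "plot_id": plot_id,
                "altitude_m": community.altitude_m[plot_id],
                "trait": trait.trait_id,
                "cwm": cwm,
                "fd_rao": fd,
                "n_species_used": n_used,
            })
    return pd.DataFrame(rows)
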