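"""Steady-state and transport statistics.

Structure is characterised by the compartment size distribution (typical
size = second over first moment), the size-weighted compositional purity of
non-vesicle compartments, and steady-state size fluctuations.  Transport is
characterised by the cargo enrichment vector (mean composition difference
between acceptor and donor over cargo-carrying vesicle transfers), its
directionality class, composition-simplex occupancy/flux maps, and the exit
kinetics of a cargo pulse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import purity_from_fractions

__all__ = [
    "TransportEvent",
    "EnrichmentVector",
    "size_distribution",
    "typical_size",
    "system_purity",
    "steady_state_stats",
    "enrichment_vector",
    "directionality",
    "simplex_grid",
    "simplex_maps",
    "exit_kinetics",
]


@dataclass(frozen=True)
class TransportEvent:
    """One cargo-carrying budding -> fusion episode."""

    time: float
    identity: int
    donor_phi: tuple[float, float, float]
    acceptor_phi: tuple[float, float, float]
    cargo: int
    back_fusion: bool = False
    is_exit: bool = False


def events_dataframe(events: list[TransportEvent]) -> pd.DataFrame:
    """Convert a list of TransportEvent to the engine's transport schema."""
    return pd.DataFrame(
        {
            "time": [e.time for e in events],
            "identity": [e.identity for e in events],
            "donor_phi_cis": [e.donor_phi[0] for e in events],
            "donor_phi_medial": [e.donor_phi[1] for e in events],
            "donor_phi_trans": [e.donor_phi[2] for e in events],
            "acceptor_phi_cis": [e.acceptor_phi[0] for e in events],
            "acceptor_phi_medial": [e.acceptor_phi[1] for e in events],
            "acceptor_phi_trans": [e.acceptor_phi[2] for e in events],
            "cargo": [e.cargo for e in events],
            "back_fusion": [e.back_fusion for e in events],
            "is_exit": [e.is_exit for e in events],
        }
    )


@dataclass(frozen=True)
class EnrichmentVector:
    """Mean acceptor-minus-donor composition difference over transfers.

    ``raw`` is the plain (weighted) mean of the per-event differences
    Δphi_i in [-1, 1]; ``normalized`` rescales it so sum_i |E_i| = 1
    (None when the raw vector vanishes).
    """

    raw: np.ndarray
    normalized: np.ndarray | None

    @property
    def e_cis(self) -> float:
        return float(self._best()[0])

    @property
    def e_medial(self) -> float:
        return float(self._best()[1])

    @property
    def e_trans(self) -> float:
        return float(self._best()[2])

    def _best(self) -> np.ndarray:
        return self.normalized if self.normalized is not None else self.raw


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

def _snapshot_sizes(snapshots: pd.DataFrame) -> np.ndarray:
    if len(snapshots) == 0:
        raise ValueError("no compartments in the provided snapshots")
    return (
        snapshots[["n_cis", "n_medial", "n_trans"]].to_numpy(dtype=np.int64).sum(axis=1)
    )


def typical_size(sizes: np.ndarray) -> float:
    """Second over first moment of the size distribution, <n^2>/<n>.

    For a distribution with an exponential large-size cut-off this sits
    near half the cut-off size.  Vesicles (size 1) are included.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("no compartments")
    return float(np.mean(sizes**2) / np.mean(sizes))


def size_distribution(snapshots: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Pooled compartment size histogram over snapshots, plus typical size.

    ``snapshots`` uses the engine schema (one row per compartment per
    snapshot time).  Returns (histogram with columns size/count/freq,
    typical size <n^2>/<n>).
    """
    sizes = _snapshot_sizes(snapshots)
    values, counts = np.unique(sizes, return_counts=True)
    hist = pd.DataFrame(
        {"size": values, "count": counts, "freq": counts / counts.sum()}
    )
    return hist, typical_size(sizes)


def system_purity(snapshot: pd.DataFrame) -> float:
    """Size-weighted mean compartment purity, ignoring vesicles.

    P_sys = sum_{n_a >= 2} n_a P_a / sum_{n_a >= 2} n_a over one snapshot.
    Returns NaN (with a warning) when only vesicles are present.
    """
    counts = snapshot[["n_cis", "n_medial", "n_trans"]].to_numpy(dtype=np.int64)
    n = counts.sum(axis=1)
    big = n >= 2
    if not np.any(big):
        warnings.warn(
            "system purity is undefined: only vesicles present", RuntimeWarning
        )
        return float("nan")
    phi = counts[big] / n[big, None]
    p = purity_from_fractions(phi)
    return float(np.sum(n[big] * p) / n[big].sum())


def steady_state_stats(
    series: pd.DataFrame,
    t_burn: float,
    column: str = "n_total",
    min_samples: int = 10,
) -> tuple[float, float]:
    """Time-average and relative SD of a scalar series past burn-in.

    Returns ``(mean, sd/mean)`` over samples with time >= t_burn.
    """
    post = series.loc[series["time"] >= t_burn, column].to_numpy(dtype=float)
    if post.size < min_samples:
        raise ValueError(
            f"only {post.size} samples after t_burn={t_burn}; need >= {min_samples}"
        )
    mean = float(post.mean())
    sd = float(post.std(ddof=0))
    return mean, (sd / mean if mean != 0 else float("nan"))


# ---------------------------------------------------------------------------
# Transport
# ---------------------------------------------------------------------------

_DONOR = ["donor_phi_cis", "donor_phi_medial", "donor_phi_trans"]
_ACCEPTOR = ["acceptor_phi_cis", "acceptor_phi_medial", "acceptor_phi_trans"]


def _select_events(
    events: pd.DataFrame,
    include_back_fusion: bool,
    include_exits: bool,
) -> pd.DataFrame:
    sel = events
    if not include_back_fusion and "back_fusion" in sel:
        sel = sel[~sel["back_fusion"].astype(bool)]
    if not include_exits and "is_exit" in sel:
        sel = sel[~sel["is_exit"].astype(bool)]
    return sel


def enrichment_vector(
    events: pd.DataFrame,
    *,
    normalize: bool = True,
    include_back_fusion: bool = True,
    include_exits: bool = False,
    cargo_weighted: bool = True,
) -> EnrichmentVector:
    """Cargo enrichment vector E over vesicle transport events.

    E_i is the mean of Δphi_i = phi_i(acceptor) - phi_i(donor), weighted by
    the cargo carried (or unweighted with ``cargo_weighted=False``).
    Boundary exits are excluded by default; vesicle back-fusion events are
    included by default (every budding/fusion episode counts).
    """
    sel = _select_events(events, include_back_fusion, include_exits)
    if len(sel) == 0:
        raise ValueError("no transport events to average over")
    dphi = sel[_ACCEPTOR].to_numpy(dtype=float) - sel[_DONOR].to_numpy(dtype=float)
    w = sel["cargo"].to_numpy(dtype=float) if cargo_weighted else np.ones(len(sel))
    raw = (w[:, None] * dphi).sum(axis=0) / w.sum()
    norm = float(np.abs(raw).sum())
    if normalize:
        if norm == 0.0:
            warnings.warn(
                "enrichment vector is exactly zero; normalization undefined",
                RuntimeWarning,
            )
            return EnrichmentVector(raw=raw, normalized=np.zeros(3))
        return EnrichmentVector(raw=raw, normalized=raw / norm)
    return EnrichmentVector(raw=raw, normalized=None)


def directionality(e: EnrichmentVector | np.ndarray) -> str:
    """Classify the net vesicular flux from the enrichment vector.

    anterograde: E_cis < 0 and E_trans > 0 (toward more mature identities);
    retrograde:  E_cis > 0 and E_trans < 0; centripetal: medial is the only
    positive gain (E_medial > 0, E_cis <= 0, E_trans <= 0); otherwise mixed.
    """
    vec = e._best() if isinstance(e, EnrichmentVector) else np.asarray(e, dtype=float)
    e_cis, e_medial, e_trans = (float(x) for x in vec)
    if e_cis < 0 and e_trans > 0:
        return "anterograde"
    if e_cis > 0 and e_trans < 0:
        return "retrograde"
    if e_medial > 0 and e_cis <= 0 and e_trans <= 0:
        return "centripetal"
    return "mixed"


# ---------------------------------------------------------------------------
# Composition-simplex maps
# ---------------------------------------------------------------------------

def simplex_grid(resolution: int) -> pd.DataFrame:
    """Barycentric bin centers of a triangular grid.

    Bins are indexed by (bin_i, bin_j) = (cis, medial) steps out of
    ``resolution``; the trans coordinate is implied.  Centers lie in the
    closed simplex.
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    rows = []
    for i in range(resolution + 1):
        for jj in range(resolution + 1 - i):
            rows.append(
                (i, jj, i / resolution, jj / resolution, (resolution - i - jj) / resolution)
            )
    return pd.DataFrame(
        rows, columns=["bin_i", "bin_j", "phi_cis", "phi_medial", "phi_trans"]
    )


def _assign_bins(phi: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Nearest bin center for each composition (ties -> lower flat index)."""
    d2 = ((phi[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def simplex_maps(
    snapshots: pd.DataFrame,
    events: pd.DataFrame,
    resolution: int = 20,
    *,
    include_exits: bool = False,
    total_cargo: float | None = None,
    duration: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Occupancy and cargo-flux fields in barycentric composition space.

    Returns ``(occupancy, arrows)``.

    ``occupancy`` has one row per grid bin: the time-averaged total patch
    content and compartment count of compartments whose composition falls
    in the bin (averaged over the distinct snapshot times), so the summed
    ``size_content`` equals the time-averaged total system size.

    ``arrows`` has one row per donor bin with at least one cargo-carrying
    event: the cargo-weighted mean acceptor composition (arrow tip) and a
    flux weight.  Back-fusion events are always excluded from arrows, and
    boundary exits are excluded by default.  When ``total_cargo`` and
    ``duration`` are given the weight is cargo transported per unit time
    divided by the total cargo count; otherwise weights are normalized to
    sum to 1.
    """
    centers_df = simplex_grid(resolution)
    centers = centers_df[["phi_cis", "phi_medial", "phi_trans"]].to_numpy()

    occupancy = centers_df.copy()
    occupancy["size_content"] = 0.0
    occupancy["count"] = 0.0
    if len(snapshots):
        counts = snapshots[["n_cis", "n_medial", "n_trans"]].to_numpy(dtype=float)
        n = counts.sum(axis=1)
        phi = counts / n[:, None]
        bins = _assign_bins(phi, centers)
        n_times = max(1, snapshots["time"].nunique())
        occupancy["size_content"] = np.bincount(
            bins, weights=n, minlength=len(centers)
        ) / n_times
        occupancy["count"] = np.bincount(bins, minlength=len(centers)) / n_times

    sel = _select_events(events, include_back_fusion=False, include_exits=include_exits)
    sel = sel[sel["cargo"] > 0] if len(sel) else sel
    arrow_rows = []
    if len(sel):
        donor_phi = sel[_DONOR].to_numpy(dtype=float)
        acceptor_phi = sel[_ACCEPTOR].to_numpy(dtype=float)
        cargo = sel["cargo"].to_numpy(dtype=float)
        donor_bins = _assign_bins(donor_phi, centers)
        for b in np.unique(donor_bins):
            mask = donor_bins == b
            w = cargo[mask]
            tip = (w[:, None] * acceptor_phi[mask]).sum(axis=0) / w.sum()
            arrow_rows.append(
                {
                    "bin_i": int(centers_df["bin_i"].iloc[b]),
                    "bin_j": int(centers_df["bin_j"].iloc[b]),
                    "base_phi_cis": centers[b, 0],
                    "base_phi_medial": centers[b, 1],
                    "base_phi_trans": centers[b, 2],
                    "tip_phi_cis": tip[0],
                    "tip_phi_medial": tip[1],
                    "tip_phi_trans": tip[2],
                    "cargo_flux": float(w.sum()),
                }
            )
    arrows = pd.DataFrame(
        arrow_rows,
        columns=[
            "bin_i", "bin_j",
            "base_phi_cis", "base_phi_medial", "base_phi_trans",
            "tip_phi_cis", "tip_phi_medial", "tip_phi_trans",
            "cargo_flux",
        ],
    )
    if len(arrows):
        if total_cargo is not None and duration is not None and total_cargo > 0:
            arrows["weight"] = arrows["cargo_flux"] / (duration * total_cargo)
        else:
            arrows["weight"] = arrows["cargo_flux"] / arrows["cargo_flux"].sum()
    else:
        arrows["weight"] = pd.Series(dtype=float)
    return occupancy, arrows


# ---------------------------------------------------------------------------
# Exit kinetics
# ---------------------------------------------------------------------------

def exit_kinetics(
    times: np.ndarray,
    remaining: np.ndarray,
    min_points: int = 5,
) -> tuple[float, float]:
    """Exponential fit of a cargo pulse's exit from the system.

    Least-squares fit of log(remaining) against time over the strictly
    positive part of the decay curve.  Returns ``(rate, r_squared)`` with
    ``rate`` the positive decay constant in units of Kf (per unit time).
    """
    times = np.asarray(times, dtype=float)
    remaining = np.asarray(remaining, dtype=float)
    mask = remaining > 0
    t, y = times[mask], np.log(remaining[mask])
    if t.size < min_points:
        raise ValueError(
            f"only {t.size} positive decay points; need >= {min_points}"
        )
    slope, intercept = np.polyfit(t, y, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(-slope), r2
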