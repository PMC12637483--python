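"""Single-allele distance quantification from nucleus/spot tables.

Input is the tabular output of a high-content imaging pipeline: one row per
segmented nucleus (area, solidity, per-channel nuclear intensity) and one
row per detected FISH spot (channel, centroid in um, intensity). The fixed
processing order is

    qc_filter_nuclei -> ploidy_filter -> match_spots -> call_contacts
    -> summarize_cells

Cross-channel DNA spots are matched one-to-one greedily in ascending
distance order; matched pairs closer than the 2 um cap are the single-allele
locus distances, and those below the 0.27 um contact threshold are DNA
contacts. Per-cell summaries carry the fraction of close alleles, nascent
RNA transcription-site metrics and nuclear GFP intensity for binned
analyses.

Tables are plain :class:`pandas.DataFrame` objects with documented schemas:

* nuclei: nucleus_id, field_id, condition, area_um2, solidity, gfp_mean
* spots: nucleus_id, channel ("dna_a" | "dna_b" | "rna"), x_um, y_um,
  intensity
* pairs: nucleus_id, distance_um, is_contact
* cells: nucleus_id, condition, n_pairs, n_contacts, fraction_close,
  rna_spot_count, rna_total_intensity, rna_mean_intensity, gfp_intensity
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .config import AnalysisConfig

DNA_CHANNELS = ("dna_a", "dna_b")


@dataclass
class FilterReport:
    """Bookkeeping for a filtering stage."""

    n_input: int
    n_kept: int
    rejected: dict[str, int] = field(default_factory=dict)


def qc_filter_nuclei(
    nuclei: pd.DataFrame, config: AnalysisConfig
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop nuclei that are too small or insufficiently solid.

    Keeps nuclei with area >= ``min_area`` and solidity >= ``min_solidity``
    (segmentation artifacts and mitotic/overlapping nuclei fail these).
    """
    small = nuclei["area_um2"] < config.min_area
    ragged = nuclei["solidity"] < config.min_solidity
    kept = nuclei[~small & ~ragged].reset_index(drop=True)
    report = FilterReport(
        n_input=len(nuclei),
        n_kept=len(kept),
        rejected={
            "area": int((small & ~ragged).sum()),
            "solidity": int((ragged & ~small).sum()),
            "both": int((small & ragged).sum()),
        },
    )
    return kept, report


def ploidy_filter(
    nuclei: pd.DataFrame, spots: pd.DataFrame, config: AnalysisConfig
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep nuclei with exactly ``ploidy`` spots in each DNA channel.

    Cells with missing (dropout) or extra (spurious/segmentation-split)
    spots in either channel are removed so every retained cell contributes a
    full complement of alleles.
    """
    counts = (
        spots[spots["channel"].isin(DNA_CHANNELS)]
        .groupby(["nucleus_id", "channel"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(DNA_CHANNELS), fill_value=0)
        .reindex(nuclei["nucleus_id"], fill_value=0)
    )
    ok = (counts == config.ploidy).all(axis=1).to_numpy()
    kept = nuclei[ok].reset_index(drop=True)
    return kept, FilterReport(
        n_input=len(nuclei), n_kept=len(kept),
        rejected={"spot_count": int((~ok).sum())},
    )


def greedy_one_to_one(dist: np.ndarray) -> list[tuple[int, int]]:
    """Greedy assignment on a distance matrix, ascending distance order.

    Repeatedly takes the globally smallest remaining distance whose row and
    column are both unused; returns (row, col) index pairs. At most
    min(n_rows, n_cols) pairs.
    """
    n_a, n_b = dist.shape
    if n_a == 0 or n_b == 0:
        return []
    order = np.argsort(dist, axis=None, kind="stable")
    used_a = np.zeros(n_a, dtype=bool)
    used_b = np.zeros(n_b, dtype=bool)
    pairs: list[tuple[int, int]] = []
    limit = min(n_a, n_b)
    for flat in order:
        i, j = divmod(int(flat), n_b)
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        pairs.append((i, j))
        if len(pairs) == limit:
            break
    return pairs


def match_spots(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    config: AnalysisConfig,
) -> np.ndarray:
    """Single-allele distances between two DNA channels of one nucleus.

    Computes all |A| x |B| Euclidean x,y distances and assigns spots
    one-to-one greedily in ascending distance order (``match_mode
    "one_to_one"``, the default) or takes each A spot's minimum distance
    (``"per_spot_min"``, for sensitivity analysis). Returns the retained
    distances, all strictly below ``max_pair_distance``.
    """
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if a.size == 0 or b.size == 0:
        return np.empty(0)
    dist = cdist(a, b)
    if config.match_mode == "per_spot_min":
        d = dist.min(axis=1)
    else:
        d = np.array([dist[i, j] for i, j in greedy_one_to_one(dist)])
    return d[d < config.max_pair_distance]


def _greedy_batch(dist: np.ndarray) -> np.ndarray:
    """Vectorized greedy one-to-one assignment on a (n, p, p) distance stack.

    Returns the (n, p) assigned distances per nucleus (greedy pick order).
    Equivalent to :func:`greedy_one_to_one` applied nucleus by nucleus.
    """
    n, p, _ = dist.shape
    work = dist.copy()
    rows = np.arange(n)
    out = np.empty((n, p))
    for step in range(p):
        flat = work.reshape(n, p * p)
        k = np.argmin(flat, axis=1)
        out[:, step] = flat[rows, k]
        i, j = np.divmod(k, p)
        work[rows, i, :] = np.inf
        work[rows, :, j] = np.inf
    return out


def match_all_nuclei(
    nuclei: pd.DataFrame, spots: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Run :func:`match_spots` per nucleus; returns the pairs table.

    Takes a vectorized path when every nucleus has the same spot count in
    both DNA channels (guaranteed after the ploidy filter); otherwise falls
    back to a per-nucleus loop. Both paths apply the same greedy rule.
    """
    dna = spots[spots["channel"].isin(DNA_CHANNELS)]
    dna = dna[dna["nucleus_id"].isin(set(nuclei["nucleus_id"]))]
    a = dna[dna["channel"] == "dna_a"].sort_values("nucleus_id", kind="stable")
    b = dna[dna["channel"] == "dna_b"].sort_values("nucleus_id", kind="stable")
    ids_a = a["nucleus_id"].to_numpy()
    ids_b = b["nucleus_id"].to_numpy()
    ua, ca = np.unique(ids_a, return_counts=True)
    ub, cb = np.unique(ids_b, return_counts=True)

    uniform = (
        len(ua) > 0 and len(ua) == len(ub) and np.array_equal(ua, ub)
        and ca.min() == ca.max() and cb.min() == cb.max()
        and ca[0] == cb[0] and config.match_mode == "one_to_one"
    )
    if uniform:
        p = int(ca[0])
        ca_xy = a[["x_um", "y_um"]].to_numpy().reshape(len(ua), p, 2)
        cb_xy = b[["x_um", "y_um"]].to_numpy().reshape(len(ua), p, 2)
        diff = ca_xy[:, :, None, :] - cb_xy[:, None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=-1))
        assigned = _greedy_batch(dist)
        keep = assigned < config.max_pair_distance
        pairs = pd.DataFrame({
            "nucleus_id": np.repeat(ua, p)[keep.ravel()],
            "distance_um": assigned.ravel()[keep.ravel()],
        })
        return call_contacts(pairs, config)

    coords_a = {nid: g[["x_um", "y_um"]].to_numpy()
                for nid, g in a.groupby("nucleus_id", observed=True)}
    coords_b = {nid: g[["x_um", "y_um"]].to_numpy()
                for nid, g in b.groupby("nucleus_id", observed=True)}
    nucleus_ids: list = []
    distances: list[np.ndarray] = []
    for nid in sorted(set(coords_a) & set(coords_b)):
        d = match_spots(coords_a[nid], coords_b[nid], config)
        nucleus_ids.extend([nid] * len(d))
        distances.append(d)
    dist = np.concatenate(distances) if distances else np.empty(0)
    pairs = pd.DataFrame({"nucleus_id": nucleus_ids, "distance_um": dist})
    return call_contacts(pairs, config)


def call_contacts(pairs: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Flag each allele pair as a DNA contact: distance strictly below the
    contact threshold (0.27 um by default)."""
    out = pairs.copy()
    out["is_contact"] = out["distance_um"] < config.contact_threshold
    return out


def summarize_cells(
    nuclei: pd.DataFrame, pairs: pd.DataFrame, rna_spots: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-cell summary: contact fraction, RNA metrics, GFP intensity.

    ``fraction_close`` is NaN for cells with zero retained pairs — no
    measurement is not the same as no contact; such cells are excluded from
    contact analyses downstream but keep their RNA metrics.
    """
    idx = nuclei["nucleus_id"]
    pair_counts = pairs.groupby("nucleus_id", observed=True).agg(
        n_pairs=("distance_um", "size"), n_contacts=("is_contact", "sum")
    ).reindex(idx, fill_value=0)
    out = pd.DataFrame({
        "nucleus_id": idx.to_numpy(),
        "condition": nuclei["condition"].to_numpy(),
        "n_pairs": pair_counts["n_pairs"].to_numpy(),
        "n_contacts": pair_counts["n_contacts"].to_numpy().astype(int),
    })
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fraction_close"] = np.where(
            out["n_pairs"] > 0, out["n_contacts"] / out["n_pairs"], np.nan
        )
    if rna_spots is None:
        rna_spots = pd.DataFrame(columns=["nucleus_id", "channel", "intensity"])
    rna = rna_spots[rna_spots.get("channel", "rna") == "rna"] \
        if "channel" in rna_spots.columns else rna_spots
    rna_agg = rna.groupby("nucleus_id", observed=True)["intensity"].agg(
        ["size", "sum", "mean"]
    ).reindex(idx)
    size = rna_agg["size"].to_numpy(dtype=float)
    out["rna_spot_count"] = np.nan_to_num(size).astype(int)
    out["rna_total_intensity"] = np.nan_to_num(
        rna_agg["sum"].to_numpy(dtype=float))
    out["rna_mean_intensity"] = rna_agg["mean"].to_numpy(dtype=float)
    out["gfp_intensity"] = nuclei["gfp_mean"].to_numpy()
    return out


def bin_cells(
    summaries: pd.DataFrame, by: str = "fraction_close", n_bins: int = 4
) -> pd.DataFrame:
    """Assign equal-count bins on ``fraction_close`` or ``gfp_intensity``.

    Bin edges are quantiles so populations stay balanced up to ties. When
    binning by contact fraction, cells with fraction_close == 0 form their
    own bin "0" (the no-contact reference population) and the remaining
    cells are quantile-split into ``n_bins - 1`` bins. Cells with NaN values
    get no bin.
    """
    if by not in ("fraction_close", "gfp_intensity"):
        raise ValueError("bin variable must be fraction_close or gfp_intensity")
    out = summaries.copy()
    values = out[by]
    labels = pd.Series(pd.NA, index=out.index, dtype="object")
    valid = values.notna()
    if by == "fraction_close":
        zero = valid & (values == 0)
        labels[zero] = "0"
        rest = valid & ~zero
        n_rest_bins = max(n_bins - 1, 1)
        labels[rest] = _quantile_labels(values[rest], n_rest_bins, offset=1)
    else:
        labels[valid] = _quantile_labels(values[valid], n_bins, offset=1)
    out[f"{by}_bin"] = labels
    return out


def _quantile_labels(values: pd.Series, n_bins: int, offset: int) -> pd.Series:
    if len(values) == 0:
        return pd.Series(dtype="object")
    if values.nunique() == 1:
        warnings.warn("constant bin variable: single bin emitted", stacklevel=3)
        return pd.Series(str(offset), index=values.index, dtype="object")
    n_bins = min(n_bins, values.nunique())
    codes = pd.qcut(values, q=n_bins, labels=False, duplicates="drop")
    return (codes + offset).astype(int).astype(str)


def condition_contact_fraction(pairs: pd.DataFrame) -> pd.DataFrame:
    """Fraction of allele pairs in contact per condition, with allele count.

    ``pairs`` must carry ``condition`` and ``is_contact`` columns (see
    :func:`attach_condition`). Empty conditions get a NaN fraction.
    """
    grouped = pairs.groupby("condition", observed=True)["is_contact"]
    out = grouped.agg(n_alleles="size", n_contacts="sum").reset_index()
    out["fraction"] = np.where(
        out["n_alleles"] > 0, out["n_contacts"] / out["n_alleles"], np.nan
    )
    return out[["condition", "fraction", "n_contacts", "n_alleles"]]


def median_pair_distance(pairs: pd.DataFrame) -> pd.DataFrame:
    """Median retained pair distance per condition (midpoint convention)."""
    out = (
        pairs.groupby("condition", observed=True)["distance_um"]
        .agg(median_um="median", n_alleles="size")
        .reset_index()
    )
    return out


def attach_condition(pairs: pd.DataFrame, nuclei: pd.DataFrame) -> pd.DataFrame:
    """Merge each pair with its nucleus' condition label."""
    return pairs.merge(
        nuclei[["nucleus_id", "condition"]], on="nucleus_id", how="left"
    )


def normalize_to_control(
    values: pd.Series, conditions: pd.Series, control: str
) -> pd.Series:
    """Divide a per-cell metric by the mean of the control condition."""
    mask = conditions == control
    if not mask.any():
        raise ValueError(f"control condition {control!r} not present")
    ref = values[mask].mean()
    if not np.isfinite(ref) or ref == 0:
        raise ValueError(f"control condition {control!r} has no usable values")
    return values / ref
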