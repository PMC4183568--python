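"""From raw electropherogram peak tables to analysable community profiles.

The processing chain applies, in order: channel/height/size filtering,
fixed-grid 2-bp binning, conversion to relative peak area, cross-sample
noise exclusion (TRFs averaging ≤5% of output where present), pooling of
split peaks that originate from one genotype, and re-normalisation. Peak
area — not height — measures abundance, since long fragments produce wider
peaks.

Peak tables are pandas DataFrames with columns
``sample_id, dye, size_bp, height, area`` (the layout of a GeneMapper
export flattened to CSV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .digest import TRFPrediction, TRFTable
from .enzymes import DEFAULT_CHANNEL_RULE

__all__ = [
    "PEAK_COLUMNS",
    "validate_peak_table",
    "filter_peaks",
    "bin_peaks",
    "profiles_to_matrix",
    "noise_filter",
    "build_pooling_map",
    "pool_split_peaks",
    "match_trfs",
    "MatchResult",
    "process_channel",
    "ChannelProfiles",
]

PEAK_COLUMNS = ["sample_id", "dye", "size_bp", "height", "area"]

KNOWN_DYES = frozenset({"HEX", "FAM"})

#: TRF drift window (bp): observed sizes run up to ~14 bp short of and at
#: most ~2 bp beyond the in silico prediction, because dye-labelled
#: fragments migrate faster than the size standard.
DEFAULT_DRIFT_WINDOW = (-14.0, 2.0)


def validate_peak_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PEAK_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peak table missing columns: {missing}")
    bad_dyes = set(table["dye"].unique()) - KNOWN_DYES
    if bad_dyes:
        raise ValueError(f"unknown dye values: {sorted(bad_dyes)}")
    if (table["size_bp"] <= 0).any():
        raise ValueError("peak sizes must be positive")
    if (table[["height", "area"]] < 0).to_numpy().any():
        raise ValueError("peak heights and areas must be non-negative")
    return table


def filter_peaks(
    table: pd.DataFrame,
    enzyme_name: str,
    min_height: float = 100.0,
    min_size: float = 100.0,
    channel_rule: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Keep peaks above the detection thresholds in the analysed channel.

    Retains rows with height strictly greater than `min_height` fluorescence
    units, size strictly greater than `min_size` bp, and the dye the channel
    rule assigns to `enzyme_name` (HEX for AluI, FAM for HinfI by default).
    """
    channel_rule = DEFAULT_CHANNEL_RULE if channel_rule is None else channel_rule
    validate_peak_table(table)
    dye = channel_rule[enzyme_name]
    keep = (
        (table["dye"] == dye)
        & (table["height"] > min_height)
        & (table["size_bp"] > min_size)
    )
    return table.loc[keep].reset_index(drop=True)


def bin_peaks(
    table: pd.DataFrame, bin_width: float = 2.0, anchor: float = 100.0
) -> pd.Series:
    """Sum peak areas on a fixed half-open bin grid anchored at `anchor`.

    Bins are [anchor, anchor+w), [anchor+w, anchor+2w), … labelled by their
    lower edge; a peak exactly on an edge falls in the bin it opens. Returns
    a Series (bin lower edge → total area), empty for an empty table.
    """
    if table.empty:
        return pd.Series(dtype=float, name="area")
    edges = anchor + bin_width * np.floor(
        (table["size_bp"].to_numpy() - anchor) / bin_width
    )
    out = (
        pd.Series(table["area"].to_numpy(), index=edges)
        .groupby(level=0)
        .sum()
        .sort_index()
    )
    out.index.name = "bin_bp"
    out.name = "area"
    return out


def profiles_to_matrix(profiles: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Stack per-sample binned area Series into a samples × bins matrix."""
    mat = pd.DataFrame(profiles).T.fillna(0.0).sort_index(axis=1)
    mat.index.name = "sample_id"
    return mat


def noise_filter(
    matrix: pd.DataFrame, threshold: float = 0.05
) -> tuple[pd.DataFrame, list[str]]:
    """Exclude low-signal TRFs and re-normalise.

    For each TRF bin the mean relative abundance is taken over the samples
    in which it is present (abundance > 0); bins whose mean is ≤ `threshold`
    are removed from every sample. Rows are re-normalised to sum to 1.
    Returns the filtered matrix and the ids of samples emptied entirely
    (their rows are left as zeros and must be handled by the caller).
    """
    if matrix.empty:
        return matrix, []
    rel = matrix.div(matrix.sum(axis=1).replace(0.0, np.nan), axis=0).fillna(0.0)
    present = rel > 0
    mean_when_present = rel.where(present).mean(axis=0, skipna=True)
    keep = mean_when_present > threshold
    filtered = rel.loc[:, keep[keep].index]
    totals = filtered.sum(axis=1)
    emptied = totals[totals <= 0].index.tolist()
    filtered = filtered.div(totals.replace(0.0, np.nan), axis=0).fillna(0.0)
    return filtered, emptied


def build_pooling_map(pairs: Iterable[tuple[float, str]]) -> dict[float, str]:
    """Assemble bin → canonical-TRF map, rejecting doubly mapped bins."""
    out: dict[float, str] = {}
    for bin_bp, label in pairs:
        if bin_bp in out and out[bin_bp] != label:
            raise ValueError(
                f"bin {bin_bp} mapped to both {out[bin_bp]!r} and {label!r}"
            )
        out[bin_bp] = label
    return out


def pool_split_peaks(
    profile: pd.Series, pooling_map: Mapping[float, str]
) -> pd.Series:
    """Combine abundances of bins that one genotype's TRF split across.

    Capillary electrophoresis can render a single TRF as 2–3 nearby peaks;
    bins mapped to the same canonical TRF label are summed. Unmapped bins
    pass through unchanged (labelled by their bin value as a string). Total
    abundance is conserved.
    """
    build_pooling_map((b, l) for b, l in pooling_map.items())  # validates
    labels = [pooling_map.get(b, f"{b:g}") for b in profile.index]
    pooled = profile.groupby(pd.Index(labels, name=profile.index.name)).sum()
    return pooled


@dataclass
class MatchResult:
    """Assignment of observed TRF bins to in silico predictions.

    ``assigned`` maps an observed bin to (genotype_id, predicted complete
    TRF); ``pseudo`` maps bins explainable only as under-digestion products
    to (genotype_id, pseudo-TRF length); ``unmatched`` lists the rest.
    """

    assigned: dict[float, tuple[str, float]] = field(default_factory=dict)
    pseudo: dict[float, tuple[str, float]] = field(default_factory=dict)
    unmatched: list[float] = field(default_factory=list)

    def pooling_map(self) -> dict[float, str]:
        """Pooling map combining split peaks of each complete TRF. Pseudo
        bins are deliberately not pooled: they are genuine extra TRFs that
        inflate observed richness."""
        return build_pooling_map(
            (b, f"{gid}@{trf:g}") for b, (gid, trf) in self.assigned.items()
        )


def match_trfs(
    observed_bins: Sequence[float],
    predictions: Sequence[TRFPrediction],
    drift_window: tuple[float, float] = DEFAULT_DRIFT_WINDOW,
) -> MatchResult:
    """Match observed TRF sizes to predictions under electrophoretic drift.

    An observed size matches a predicted complete TRF when
    ``lo <= observed − predicted <= hi``; among candidates the smallest
    absolute deviation wins, ties going to the smaller predicted size. Sizes
    matching only pseudo-TRF predictions are flagged ``pseudo``; the rest
    are unmatched.
    """
    lo, hi = drift_window
    if not lo < hi:
        raise ValueError("drift window lower bound must be below upper bound")
    complete = [(p.genotype_id, p.complete_trf_bp) for p in predictions]
    pseudo = [
        (p.genotype_id, pl) for p in predictions for pl in sorted(p.pseudo_trfs_bp)
    ]
    result = MatchResult()
    for obs in observed_bins:
        cands = [
            (abs(obs - trf), trf, gid)
            for gid, trf in complete
            if lo <= obs - trf <= hi
        ]
        if cands:
            _, trf, gid = min(cands)
            result.assigned[obs] = (gid, trf)
            continue
        pcands = [
            (abs(obs - pl), pl, gid) for gid, pl in pseudo if lo <= obs - pl <= hi
        ]
        if pcands:
            _, pl, gid = min(pcands)
            result.pseudo[obs] = (gid, pl)
        else:
            result.unmatched.append(obs)
    return result


@dataclass
class ChannelProfiles:
    """Fully processed profiles for one enzyme channel.

    ``matrix``: samples × TRF labels, rows summing to 1.
    ``raw_totals``: total filtered peak area per sample (the fluorescence
    'sample size' used for richness-weighted diversity).
    ``match``: bin assignment against predictions, if a TRF table was given.
    ``emptied``: samples whose profile vanished during filtering.
    """

    enzyme_name: str
    matrix: pd.DataFrame
    raw_totals: pd.Series
    match: MatchResult | None = None
    emptied: list[str] = field(default_factory=list)


def process_channel(
    peaks: pd.DataFrame,
    enzyme_name: str,
    trf_table: TRFTable | None = None,
    *,
    min_height: float = 100.0,
    min_size: float = 100.0,
    bin_width: float = 2.0,
    noise_threshold: float = 0.05,
    drift_window: tuple[float, float] = DEFAULT_DRIFT_WINDOW,
    channel_rule: Mapping[str, str] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> ChannelProfiles:
    """Run the full processing chain for one enzyme channel.

    Order of operations: channel/height/size filter → 2-bp binning →
    relative abundance → cross-sample noise filter → split-peak pooling
    (when `trf_table` provides predictions to pool against) →
    re-normalisation. `sample_ids` fixes the sample set (samples with no
    surviving peaks are reported in ``emptied``).
    """
    filtered = filter_peaks(peaks, enzyme_name, min_height, min_size, channel_rule)
    ids = list(sample_ids) if sample_ids is not None else sorted(
        peaks["sample_id"].unique()
    )
    profiles = {
        sid: bin_peaks(filtered[filtered["sample_id"] == sid], bin_width)
        for sid in ids
    }
    matrix = profiles_to_matrix(profiles)
    raw_totals = matrix.sum(axis=1)
    matrix, emptied = noise_filter(matrix, noise_threshold)
    match = None
    if trf_table is not None and not matrix.empty:
        match = match_trfs(
            [float(b) for b in matrix.columns],
            trf_table.for_enzyme(enzyme_name),
            drift_window,
        )
        pmap = match.pooling_map()
        matrix = pd.DataFrame(
            {sid: pool_split_peaks(matrix.loc[sid], pmap) for sid in matrix.index}
        ).T.fillna(0.0)
        matrix.index.name = "sample_id"
    else:
        matrix = matrix.rename(columns=lambda b: f"{b:g}")
    totals = matrix.sum(axis=1)
    matrix = matrix.div(totals.replace(0.0, np.nan), axis=0).fillna(0.0)
    return ChannelProfiles(
        enzyme_name=enzyme_name,
        matrix=matrix,
        raw_totals=raw_totals,
        match=match,
        emptied=sorted(set(emptied) | {s for s, t in totals.items() if t <= 0}),
    )
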