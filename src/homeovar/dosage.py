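"""Homoeolog dosage calling from WGS read-depth ratios.

Homoeologous exchanges (HEs) duplicate one subgenome's segment while
deleting the other's, shifting the per-pair copy ratio away from the
balanced 2:2 state of a tetraploid. The caller works entirely in
gene-rank coordinates along each homoeologous chromosome pair:

1. per pair, the BnC depth fraction ``depth_C / (depth_C + depth_A)``;
2. sliding-window smoothing of that fraction along the chromosome pair
   (every pair is averaged over all windows that cover it, so the
   effective kernel is triangular);
3. quintile classification of the smoothed fraction into the dosage
   classes 0:4, 1:3, 2:2, 3:1, 4:0 (BnC:BnA) — 0-20% is 0:4, 20-40% is
   1:3, and so on, with the top bin closed at 1.0;
4. a minimum-run rule: only 10 or more consecutive genes in the same
   non-2:2 class constitute an HE segment; shorter runs are relabeled
   2:2 so every pair retains a final class;
5. chromosome-scale exclusion: chromosome pairs that are skewed over the
   majority of their genes in a sample are flagged (likely aneuploidy or
   whole-chromosome events rather than segmental HE), and excluded for
   all samples when the majority of samples is affected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

log = logging.getLogger(__name__)

DOSAGE_CLASSES = ("0:4", "1:3", "2:2", "3:1", "4:0")
HE_CLASSES = ("0:4", "1:3", "3:1", "4:0")
BALANCED = "2:2"

_QUINTILE_EDGES = np.array([0.2, 0.4, 0.6, 0.8])
_CLASS_ARRAY = np.array(DOSAGE_CLASSES, dtype=object)


@dataclass(frozen=True)
class HESegment:
    """A maximal run of >= min_run consecutive pairs in one non-2:2 class.

    Coordinates are 0-based half-open in order_index units.
    """

    sample_id: str
    chrom_pair: str
    start_index: int
    end_index: int
    dosage_class: str

    def __post_init__(self):
        if self.end_index <= self.start_index:
            raise ValidationError(
                f"segment end ({self.end_index}) must exceed start "
                f"({self.start_index})"
            )
        if self.dosage_class not in HE_CLASSES:
            raise ValidationError(
                f"HE segment class must be one of {HE_CLASSES}, "
                f"got {self.dosage_class!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.end_index - self.start_index


@dataclass(frozen=True)
class ChromExclusion:
    """A chromosome pair excluded from downstream expression analysis.

    ``sample_id is None`` means the exclusion applies to every sample
    (the chromosome was skewed in the majority of samples); otherwise it
    applies to that sample only. ``fraction`` records the share of
    non-missing pairs that were non-2:2 in the flagged sample(s).
    """

    chrom_pair: str
    sample_id: str | None
    fraction: float

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValidationError("exclusion fraction must lie in [0, 1]")


def depth_ratio(depth_C, depth_A):
    """BnC depth fraction depth_C / (depth_C + depth_A).

    NaN where the total depth is zero (undefined ratio). Accepts scalars
    or arrays; negative depths are a validation error.
    """
    c = np.asarray(depth_C, dtype=float)
    a = np.asarray(depth_A, dtype=float)
    if (c < 0).any() or (a < 0).any():
        raise ValidationError("read depths must be non-negative")
    total = c + a
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, c / np.where(total > 0, total, 1.0), np.nan)
    if np.ndim(depth_C) == 0 and np.ndim(depth_A) == 0:
        return float(ratio)
    return ratio


def smooth_ratios(ratios, window: int = 170, step: int = 1) -> np.ndarray:
    """Sliding-window smoothing of per-pair depth ratios.

    Each pair's smoothed value is the mean of the window means over all
    full windows that contain it; missing (NaN) ratios are ignored inside
    a window, and a pair is missing only if every covering window is
    all-missing. Pairs near chromosome ends are covered by fewer windows
    (the truncated window set). If the window exceeds the chromosome
    length, a single whole-chromosome window is used, with a warning.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    if step < 1:
        raise ValidationError("step must be >= 1")
    r = np.asarray(ratios, dtype=float)
    n = r.size
    if n == 0:
        return r.copy()
    if window > n:
        log.warning(
            "window (%d) exceeds chromosome length (%d); using one "
            "whole-chromosome window", window, n,
        )
        window = n
    valid = ~np.isnan(r)
    vals = np.where(valid, r, 0.0)
    cs = np.concatenate([[0.0], np.cumsum(vals)])
    cn = np.concatenate([[0], np.cumsum(valid)])
    starts = np.arange(0, n - window + 1, step)
    wsum = cs[starts + window] - cs[starts]
    wcnt = cn[starts + window] - cn[starts]
    with np.errstate(invalid="ignore"):
        wmean = np.where(wcnt > 0, wsum / np.maximum(wcnt, 1), np.nan)

    # average window means over the windows covering each pair
    wvalid = ~np.isnan(wmean)
    ws = np.concatenate([[0.0], np.cumsum(np.where(wvalid, wmean, 0.0))])
    wn = np.concatenate([[0], np.cumsum(wvalid)])
    idx = np.arange(n)
    lo = np.searchsorted(starts, idx - window + 1, side="left")
    hi = np.searchsorted(starts, idx, side="right")
    cnt = wn[hi] - wn[lo]
    total = ws[hi] - ws[lo]
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, total / np.maximum(cnt, 1), np.nan)
    return out


def assign_dosage_class(smoothed_ratio):
    """Map a smoothed BnC fraction to a dosage class by equal quintiles.

    [0, 0.2) -> 0:4, [0.2, 0.4) -> 1:3, [0.4, 0.6) -> 2:2,
    [0.6, 0.8) -> 3:1, [0.8, 1.0] -> 4:0. NaN stays missing (None);
    ratios outside [0, 1] are a validation error.
    """
    arr = np.asarray(smoothed_ratio, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    valid = ~np.isnan(arr)
    if ((arr[valid] < 0) | (arr[valid] > 1)).any():
        raise ValidationError("smoothed ratio outside [0, 1]")
    idx = np.searchsorted(_QUINTILE_EDGES, arr, side="right")
    out = np.full(arr.shape, None, dtype=object)
    out[valid] = _CLASS_ARRAY[idx[valid]]
    return out[0] if scalar else out


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value))


def call_segments(
    classes: Sequence,
    order_index: Sequence[int] | None = None,
    *,
    sample_id: str = "",
    chrom_pair: str = "",
    min_run: int = 10,
) -> tuple[np.ndarray, list[HESegment]]:
    """Apply the minimum-run rule along one chromosome pair and sample.

    ``classes`` must be ordered by order_index. Maximal runs of one
    identical non-2:2 class with length >= ``min_run`` become HESegments;
    shorter non-2:2 runs are relabeled 2:2 ("not HE") so every observed
    pair carries a final class. Missing states break runs and stay
    missing. Returns (final classes, segments).
    """
    arr = np.array(list(classes), dtype=object)
    n = arr.size
    if order_index is None:
        order = np.arange(n)
    else:
        order = np.asarray(order_index, dtype=int)
        if order.size != n:
            raise ValidationError("order_index and classes length mismatch")
    final = arr.copy()
    segments: list[HESegment] = []
    i = 0
    while i < n:
        c = arr[i]
        if _is_missing(c):
            i += 1
            continue
        j = i + 1
        while j < n and not _is_missing(arr[j]) and arr[j] == c:
            j += 1
        if c != BALANCED:
            if j - i >= min_run:
                segments.append(
                    HESegment(
                        sample_id=sample_id,
                        chrom_pair=chrom_pair,
                        start_index=int(order[i]),
                        end_index=int(order[j - 1]) + 1,
                        dosage_class=str(c),
                    )
                )
            else:
                final[i:j] = BALANCED
        i = j
    return final, segments


def call_dosage(
    pairs: pd.DataFrame,
    depths: pd.DataFrame,
    *,
    window: int = 170,
    step: int = 1,
    min_run: int = 10,
) -> tuple[pd.DataFrame, list[HESegment]]:
    """Run the full dosage-calling chain over a depth table.

    Parameters
    ----------
    pairs
        Pair map as returned by :func:`homeovar.io.read_pair_table`
        (must carry chrom_pair and order_index).
    depths
        Long table (sample_id, pair_id, depth_C, depth_A); every pair_id
        must resolve to a pair in ``pairs``.

    Returns
    -------
    states, segments
        ``states`` has one row per (sample, pair) with raw_ratio,
        smoothed_ratio and the final dosage_class; ``segments`` are the
        called HE segments across all samples.
    """
    pair_cols = pairs[["pair_id", "chrom_pair", "order_index"]]
    merged = depths.merge(pair_cols, on="pair_id", how="left")
    unresolved = merged["chrom_pair"].isna()
    if unresolved.any():
        bad = merged.loc[unresolved, "pair_id"].unique()[:5].tolist()
        raise ValidationError(f"depth table pair_id(s) not in pair map: {bad}")
    merged["raw_ratio"] = depth_ratio(
        merged["depth_C"].to_numpy(), merged["depth_A"].to_numpy()
    )
    merged = merged.sort_values(
        ["sample_id", "chrom_pair", "order_index"], kind="mergesort"
    ).reset_index(drop=True)

    smoothed = np.empty(len(merged))
    final_class = np.empty(len(merged), dtype=object)
    segments: list[HESegment] = []
    for (sample_id, chrom_pair), idx in merged.groupby(
        ["sample_id", "chrom_pair"], sort=False
    ).indices.items():
        raw = merged["raw_ratio"].to_numpy()[idx]
        sm = smooth_ratios(raw, window=window, step=step)
        cls = assign_dosage_class(sm)
        order = merged["order_index"].to_numpy()[idx]
        final, segs = call_segments(
            cls, order, sample_id=sample_id, chrom_pair=chrom_pair,
            min_run=min_run,
        )
        smoothed[idx] = sm
        final_class[idx] = final
        segments.extend(segs)
    states = merged[
        ["sample_id", "pair_id", "chrom_pair", "order_index", "raw_ratio"]
    ].copy()
    states["smoothed_ratio"] = smoothed
    states["dosage_class"] = final_class
    return states, segments


def flag_chromosome_scale(
    states: pd.DataFrame,
    *,
    gene_majority: float = 0.5,
    sample_majority: float = 0.5,
) -> list[ChromExclusion]:
    """Flag chromosome pairs whose depth skew is chromosome-scale.

    A chromosome pair is flagged for a sample when more than
    ``gene_majority`` of its non-missing pairs are non-2:2; if more than
    ``sample_majority`` of the samples are flagged the chromosome is
    excluded for all samples, otherwise only for the flagged samples.
    These events look like aneuploidy or near-whole-chromosome
    duplication/deletion rather than segmental HE and would confound the
    expression-response analysis.
    """
    cls = states["dosage_class"]
    observed = cls.notna()
    skewed = observed & (cls != BALANCED)
    per = (
        pd.DataFrame(
            {
                "chrom_pair": states["chrom_pair"],
                "observed": observed.astype(int),
                "skewed": skewed.astype(int),
                "sample_id": states["sample_id"],
            }
        )
        .groupby(["chrom_pair", "sample_id"], sort=True)[["observed", "skewed"]]
        .sum()
    )
    with np.errstate(invalid="ignore"):
        per["fraction"] = np.where(
            per["observed"] > 0, per["skewed"] / per["observed"].clip(lower=1), 0.0
        )
    per["flagged"] = per["fraction"] > gene_majority

    exclusions: list[ChromExclusion] = []
    for chrom_pair, grp in per.groupby(level="chrom_pair", sort=True):
        n_samples = len(grp)
        flagged = grp[grp["flagged"]]
        if n_samples and len(flagged) / n_samples > sample_majority:
            exclusions.append(
                ChromExclusion(
                    chrom_pair=chrom_pair,
                    sample_id=None,
                    fraction=float(flagged["fraction"].mean()),
                )
            )
        else:
            for (_, sample_id), row in flagged.iterrows():
                exclusions.append(
                    ChromExclusion(
                        chrom_pair=chrom_pair,
                        sample_id=sample_id,
                        fraction=float(row["fraction"]),
                    )
                )
    if exclusions:
        log.info("chromosome-scale exclusions: %d", len(exclusions))
    return exclusions


def apply_exclusions(
    df: pd.DataFrame, exclusions: Iterable[ChromExclusion]
) -> pd.DataFrame:
    """Drop rows on excluded chromosome pairs.

    ``df`` needs chrom_pair and sample_id columns; all-sample exclusions
    remove the chromosome everywhere, per-sample exclusions only there.
    """
    exclusions = list(exclusions)
    if not exclusions:
        return df
    drop = pd.Series(False, index=df.index)
    for exc in exclusions:
        hit = df["chrom_pair"] == exc.chrom_pair
        if exc.sample_id is not None:
            hit &= df["sample_id"] == exc.sample_id
        drop |= hit
    n = int(drop.sum())
    if n:
        log.info("excluding %d rows on chromosome-scale flagged chromosomes", n)
    return df[~drop]


def exclusions_frame(exclusions: Iterable[ChromExclusion]) -> pd.DataFrame:
    """Tabulate exclusions for TSV output (sample_id 'all' = every sample)."""
    rows = [
        (e.chrom_pair, "all" if e.sample_id is None else e.sample_id, e.fraction)
        for e in exclusions
    ]
    return pd.DataFrame(rows, columns=["chrom_pair", "sample_id", "fraction"])
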