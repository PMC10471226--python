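"""Per-pair expression responses to HE and WGD and per-GO-term variance.

The expression response of a homoeolog pair is the fold change of its
summed expression against a parental baseline:

* HE mode: (tpm_C + tpm_A) / (tpm_oleracea + tpm_rapa) — the summed
  progenitor expression stands in for the balanced 2:2 state, so a
  dosage-neutral pair has fold change 1;
* WGD mode: (tpm_C + tpm_A) / midparent, midparent being half the
  parental sum — exact dosage doubling gives fold change 2.

The two definitions satisfy fold_change_wgd == 2 * fold_change_he
identically.

Per GO term and stratum, the coefficient of variation (sample SD / mean)
of these fold changes is the HE response variance (HERV, HE mode) or the
polyploid response variance (PRV, WGD mode). Dosage balance selection is
expected to make the response of dosage-sensitive (class II) GO terms
less variable than that of dosage-insensitive (class I) terms.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from . import dosage as _dosage
from .errors import ValidationError
from .stats import TestResult, kruskal_wallis

log = logging.getLogger(__name__)

BIAS_CLASSES = ("BnC", "BnA", "unbiased")
RECORD_COLUMNS = [
    "pair_id", "sample_id", "generation", "mode", "dosage_class",
    "fold_change", "bias_class",
]
GO_CV_COLUMNS = ["go_id", "go_class", "n_pairs", "n_obs", "cv"]


def filter_expressed_pairs(
    expression: pd.DataFrame, min_sum_tpm: float = 10.0
) -> pd.DataFrame:
    """Drop lowly expressed pairs: summed homoeolog TPM below threshold.

    The filter is on the pair sum only, deliberately allowing one copy to
    be truly silenced. Applied per (sample, pair) row.
    """
    total = expression["tpm_C"].to_numpy(float) + expression["tpm_A"].to_numpy(float)
    keep = total >= min_sum_tpm
    out = expression[keep]
    dropped = int((~keep).sum())
    if dropped:
        log.info("expression filter: dropped %d rows with summed TPM < %g",
                 dropped, min_sum_tpm)
    if out.empty:
        log.warning("expression filter removed every pair (min_sum_tpm=%g)",
                    min_sum_tpm)
    return out


def fold_change_he(tpm_C, tpm_A, tpm_oleracea, tpm_rapa):
    """Fold change of summed pair expression vs summed parental expression.

    NaN (excluded) where the parental sum is zero. Vectorised; scalars in,
    scalar out.
    """
    c, a = np.asarray(tpm_C, float), np.asarray(tpm_A, float)
    o, r = np.asarray(tpm_oleracea, float), np.asarray(tpm_rapa, float)
    if (c < 0).any() or (a < 0).any() or (o < 0).any() or (r < 0).any():
        raise ValidationError("TPM values must be non-negative")
    den = o + r
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        fc = np.where(den > 0, (c + a) / np.where(den > 0, den, 1.0), np.nan)
    if np.ndim(tpm_C) == 0 and np.ndim(tpm_rapa) == 0:
        return float(fc)
    return fc


def fold_change_wgd(tpm_C, tpm_A, tpm_oleracea, tpm_rapa):
    """Fold change of summed pair expression vs midparent expression.

    Midparent is (tpm_oleracea + tpm_rapa) / 2, so this is exactly twice
    :func:`fold_change_he`. NaN where the midparent is zero.
    """
    fc = fold_change_he(tpm_C, tpm_A, tpm_oleracea, tpm_rapa)
    return 2.0 * fc


def classify_parental_bias(
    tpm_oleracea,
    tpm_rapa,
    threshold_log2fc: float = 3.5,
    pseudocount: float = 0.01,
):
    """Classify homoeolog expression bias from progenitor orthologs.

    log2((oleracea + eps) / (rapa + eps)) strictly above the threshold is
    BnC-biased (the C subgenome descends from B. oleracea), strictly
    below the negated threshold is BnA-biased, anything else unbiased.
    Boundary values are unbiased. A pair with both parents at zero is
    unclassifiable (None) and excluded from bias strata. The pseudocount
    tolerates single-zero parents.
    """
    o = np.asarray(tpm_oleracea, float)
    r = np.asarray(tpm_rapa, float)
    if (o < 0).any() or (r < 0).any():
        raise ValidationError("TPM values must be non-negative")
    scalar = o.ndim == 0 and r.ndim == 0
    o, r = np.atleast_1d(o), np.atleast_1d(r)
    o, r = np.broadcast_arrays(o, r)
    log2fc = np.log2((o + pseudocount) / (r + pseudocount))
    out = np.full(log2fc.shape, "unbiased", dtype=object)
    out[log2fc > threshold_log2fc] = "BnC"
    out[log2fc < -threshold_log2fc] = "BnA"
    out[(o == 0) & (r == 0)] = None
    return out[0] if scalar else out


def transfer_go_annotations(
    pairs: pd.DataFrame,
    go_table: pd.DataFrame,
    ortholog_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Resolve GO assignments onto homoeolog pairs.

    ``go_table`` rows carry (gene_id, go_id, go_class) where gene_id may
    be a pair id, a BnC (B. oleracea) gene id, a BnA (B. rapa) gene id,
    or an A. thaliana gene id resolvable through ``ortholog_map``
    (thaliana_gene -> oleracea_gene -> pair). One-to-many ortholog hits
    annotate every target pair (union), which is logged. Returns unique
    (pair_id, go_id, go_class) rows; unresolvable gene ids are dropped.
    """
    frames = [
        pd.DataFrame({"gene_id": pairs["pair_id"], "pair_id": pairs["pair_id"]}),
        pd.DataFrame({"gene_id": pairs["gene_C"], "pair_id": pairs["pair_id"]}),
        pd.DataFrame({"gene_id": pairs["gene_A"], "pair_id": pairs["pair_id"]}),
    ]
    if ortholog_map is not None and len(ortholog_map):
        chained = ortholog_map.merge(
            pd.DataFrame({"oleracea_gene": pairs["gene_C"],
                          "pair_id": pairs["pair_id"]}),
            on="oleracea_gene",
        )
        multi = chained["thaliana_gene"].duplicated().sum()
        if multi:
            log.info(
                "ortholog map: %d one-to-many thaliana hits annotate all targets",
                int(multi),
            )
        frames.append(chained.rename(columns={"thaliana_gene": "gene_id"})[
            ["gene_id", "pair_id"]
        ])
    lookup = pd.concat(frames, ignore_index=True).drop_duplicates()
    resolved = go_table.merge(lookup, on="gene_id", how="left")
    missing = resolved["pair_id"].isna()
    if missing.any():
        log.info("GO transfer: %d assignment rows had unresolvable gene ids",
                 int(missing.sum()))
    out = (
        resolved[~missing][["pair_id", "go_id", "go_class"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    return out


def build_response_records(
    expression: pd.DataFrame,
    parental: pd.DataFrame,
    states: pd.DataFrame,
    sample_meta: pd.DataFrame,
    mode: str,
    *,
    min_sum_tpm: float = 10.0,
    bias_threshold_log2fc: float = 3.5,
    pseudocount: float = 0.01,
    exclusions: Iterable[_dosage.ChromExclusion] = (),
) -> pd.DataFrame:
    """Assemble per-(pair, sample) expression-response records.

    HE mode keeps (pair, sample) observations whose called dosage class is
    a non-2:2 HE class and takes the fold change against the summed
    parents; WGD mode keeps 2:2 observations (a pair need not be 2:2 in
    every sample to contribute from the samples where it is) against the
    midparent. Chromosome-scale exclusions are applied to both datasets
    before anything else so that downstream HE-vs-WGD comparisons share
    the same gene universe. Records with an undefined baseline are
    dropped and counted in the log.
    """
    if mode not in ("HE", "WGD"):
        raise ValidationError(f"mode must be 'HE' or 'WGD', got {mode!r}")
    expr = filter_expressed_pairs(expression, min_sum_tpm)
    par = parental
    if par["pair_id"].duplicated().any():
        par = par.groupby("pair_id", as_index=False)[
            ["tpm_oleracea", "tpm_rapa"]
        ].mean()
    df = expr.merge(
        states[["sample_id", "pair_id", "chrom_pair", "dosage_class"]],
        on=["sample_id", "pair_id"],
        how="inner",
    )
    df = _dosage.apply_exclusions(df, exclusions)
    df = df.merge(par, on="pair_id", how="inner")
    df = df.merge(sample_meta[["sample_id", "generation"]], on="sample_id",
                  how="left")
    if df["generation"].isna().any():
        missing = df.loc[df["generation"].isna(), "sample_id"].unique()[:5]
        raise ValidationError(f"samples missing from metadata: {list(missing)}")

    observed = df["dosage_class"].notna()
    if mode == "HE":
        keep = observed & df["dosage_class"].isin(_dosage.HE_CLASSES)
        fc_fun = fold_change_he
    else:
        keep = observed & (df["dosage_class"] == _dosage.BALANCED)
        fc_fun = fold_change_wgd
    df = df[keep].copy()
    fc = fc_fun(
        df["tpm_C"].to_numpy(), df["tpm_A"].to_numpy(),
        df["tpm_oleracea"].to_numpy(), df["tpm_rapa"].to_numpy(),
    )
    df["fold_change"] = fc
    undefined = df["fold_change"].isna()
    if undefined.any():
        log.info("%s records: dropped %d with zero parental baseline",
                 mode, int(undefined.sum()))
        df = df[~undefined]
    df["bias_class"] = classify_parental_bias(
        df["tpm_oleracea"].to_numpy(), df["tpm_rapa"].to_numpy(),
        threshold_log2fc=bias_threshold_log2fc, pseudocount=pseudocount,
    )
    df["mode"] = mode
    df["generation"] = df["generation"].astype(int)
    return df[RECORD_COLUMNS].reset_index(drop=True)


def filter_stratum(
    records: pd.DataFrame,
    *,
    bias: str = "all",
    generation: int | str = "all",
    dosage: str = "all",
) -> pd.DataFrame:
    """Restrict response records to one analysis stratum.

    ``bias`` in {all, BnC, BnA, unbiased}; ``generation`` in
    {all, 1, 5, 10}; ``dosage`` a dosage-class string or "all". Bias
    strata exclude unclassifiable pairs.
    """
    out = records
    if bias != "all":
        if bias not in BIAS_CLASSES:
            raise ValidationError(f"unknown bias stratum {bias!r}")
        out = out[out["bias_class"] == bias]
    if generation != "all":
        out = out[out["generation"] == int(generation)]
    if dosage != "all":
        if dosage not in _dosage.DOSAGE_CLASSES:
            raise ValidationError(f"unknown dosage class {dosage!r}")
        out = out[out["dosage_class"] == dosage]
    return out


def group_response_variance(
    records: pd.DataFrame,
    go_map: pd.DataFrame,
    *,
    min_go_genes: int = 20,
    collapse_pairs: str | None = None,
) -> pd.DataFrame:
    """Per-GO-term coefficient of variation of fold changes (HERV/PRV).

    Each (pair, sample) fold change is one observation by default; with
    ``collapse_pairs="mean"`` fold changes are first averaged per pair.
    GO terms contributing fewer than ``min_go_genes`` distinct pairs are
    dropped: the size filter counts genes, not observations. Returns a
    frame with go_id, go_class, n_pairs, n_obs, cv.
    """
    if collapse_pairs not in (None, "mean"):
        raise ValidationError(f"collapse_pairs must be None or 'mean'")
    df = records.merge(go_map, on="pair_id", how="inner")
    if df.empty:
        return pd.DataFrame(columns=GO_CV_COLUMNS)
    if collapse_pairs == "mean":
        df = (
            df.groupby(["go_id", "go_class", "pair_id"], as_index=False)
            ["fold_change"].mean()
        )
    grouped = df.groupby(["go_id", "go_class"])
    agg = grouped["fold_change"].agg(["count", "mean", "std"])
    agg["n_pairs"] = grouped["pair_id"].nunique()
    agg = agg[(agg["n_pairs"] >= min_go_genes) & (agg["count"] >= 2)]
    if agg.empty:
        return pd.DataFrame(columns=GO_CV_COLUMNS)
    agg = agg.reset_index()
    agg["cv"] = agg["std"] / agg["mean"]
    out = agg.rename(columns={"count": "n_obs"})[GO_CV_COLUMNS]
    return out.sort_values(["go_class", "go_id"], kind="mergesort").reset_index(
        drop=True
    )


def class_comparison(go_cv: pd.DataFrame) -> TestResult:
    """Kruskal-Wallis of per-GO CVs between class I and class II terms."""
    g1 = go_cv.loc[go_cv["go_class"] == "I", "cv"].to_numpy()
    g2 = go_cv.loc[go_cv["go_class"] == "II", "cv"].to_numpy()
    if g1.size == 0 or g2.size == 0:
        raise ValidationError(
            "class comparison requires GO terms in both classes "
            f"(I: {g1.size}, II: {g2.size})"
        )
    res = kruskal_wallis([g1, g2])
    direction = _direction(g1, g2)
    return TestResult(
        res.test_name, res.statistic, res.p_value, res.group_sizes,
        direction=direction,
    )


def compare_class_expression(
    expression: pd.DataFrame,
    go_map: pd.DataFrame,
    *,
    min_go_genes: int = 20,
) -> TestResult:
    """Confound check: do class I and class II GO terms differ in mean TPM?

    Lower expression generally means higher measurement variance, so a
    CV difference between classes could be an expression artifact. Per
    GO term the mean summed-pair TPM over its (pair, sample) rows is
    computed; the two classes' per-GO means are compared with a
    Kruskal-Wallis test. Units are per-GO-term means, matching the CV
    analysis where each GO term is one observation.
    """
    df = expression.copy()
    df["tpm_sum"] = df["tpm_C"].astype(float) + df["tpm_A"].astype(float)
    df = df.merge(go_map, on="pair_id", how="inner")
    if df.empty:
        raise ValidationError("no expression rows map to GO terms")
    grouped = df.groupby(["go_id", "go_class"])
    per_go = grouped["tpm_sum"].mean().to_frame("mean_tpm")
    per_go["n_pairs"] = grouped["pair_id"].nunique()
    per_go = per_go[per_go["n_pairs"] >= min_go_genes].reset_index()
    if len(per_go) < 2:
        raise ValidationError(
            f"need at least 2 GO terms passing the size filter, "
            f"got {len(per_go)}"
        )
    g1 = per_go.loc[per_go["go_class"] == "I", "mean_tpm"].to_numpy()
    g2 = per_go.loc[per_go["go_class"] == "II", "mean_tpm"].to_numpy()
    if g1.size == 0 or g2.size == 0:
        raise ValidationError("a dosage class has no GO terms passing filters")
    res = kruskal_wallis([g1, g2])
    return TestResult(
        res.test_name, res.statistic, res.p_value, res.group_sizes,
        direction=_direction(g1, g2),
    )


def _direction(g1: np.ndarray, g2: np.ndarray) -> str:
    """Describe which class sits lower (I = insensitive, II = sensitive)."""
    m1, m2 = np.median(g1), np.median(g2)
    if m2 < m1:
        return "II < I"
    if m1 < m2:
        return "I < II"
    return "none"
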