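"""End-to-end orchestration: dosage calling, HERV, PRV and the
HE-vs-WGD imbalance comparison, with a reproducible run manifest.

The three analyses share one filter chain so that comparisons between
the HE and the balanced 2:2 datasets are apples-to-apples: the same
expression filter (summed TPM), the same chromosome-scale exclusions and
the same GO universe apply to both.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import __version__
from . import dosage as _dosage
from . import response as _response
from . import stats as _stats
from .errors import ValidationError

log = logging.getLogger(__name__)

HE_DOSAGE_GROUPS = ("0:4", "1:3", "3:1", "4:0")


@dataclass
class PipelineParams:
    """Tunable parameters of the full analysis, with the study defaults."""

    window: int = 170
    step: int = 1
    min_run: int = 10
    gene_majority: float = 0.5
    sample_majority: float = 0.5
    min_sum_tpm: float = 10.0
    min_go_genes: int = 20
    bias_threshold_log2fc: float = 3.5
    pseudocount: float = 0.01
    collapse_pairs: str | None = None
    adjust: str = "none"

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineParams":
        return cls(**{k: v for k, v in raw.items()})


@dataclass
class PipelineResult:
    """Everything one run computes, plus the filter-cascade manifest."""

    states: pd.DataFrame
    segments: list
    exclusions: list
    he_records: pd.DataFrame
    wgd_records: pd.DataFrame
    herv: pd.DataFrame            # per-GO CV rows, tagged by stratum
    herv_tests: pd.DataFrame
    prv: pd.DataFrame
    prv_tests: pd.DataFrame
    imbalance_tests: pd.DataFrame
    imbalance_cv: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _strata(meta: pd.DataFrame) -> list[dict]:
    """The analysis panels: pooled, per bias class, per generation."""
    strata = [{"bias": "all", "generation": "all"}]
    strata += [{"bias": b, "generation": "all"}
               for b in _response.BIAS_CLASSES]
    strata += [{"bias": "all", "generation": int(g)}
               for g in sorted(meta["generation"].unique())]
    return strata


def _stratified_variance(
    records: pd.DataFrame,
    go_map: pd.DataFrame,
    params: PipelineParams,
    strata: Iterable[dict],
    label: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-GO CVs and the class I vs class II test for every stratum."""
    cv_frames, test_rows = [], []
    for stratum in strata:
        sub = _response.filter_stratum(records, **stratum)
        go_cv = _response.group_response_variance(
            sub, go_map, min_go_genes=params.min_go_genes,
            collapse_pairs=params.collapse_pairs,
        )
        tag = f"bias={stratum['bias']},generation={stratum['generation']}"
        if go_cv.empty:
            log.warning("%s stratum %s: no GO terms pass filters", label, tag)
            continue
        go_cv = go_cv.assign(bias=stratum["bias"],
                             generation=str(stratum["generation"]))
        cv_frames.append(go_cv)
        try:
            res = _response.class_comparison(go_cv)
        except ValidationError as exc:
            log.warning("%s stratum %s: %s", label, tag, exc)
            continue
        test_rows.append(
            (tag, res.test_name, res.group_sizes[0], res.group_sizes[1],
             res.statistic, res.p_value, res.stars, res.direction or "")
        )
    cv = (pd.concat(cv_frames, ignore_index=True) if cv_frames
          else pd.DataFrame(columns=_response.GO_CV_COLUMNS + ["bias",
                                                               "generation"]))
    tests = pd.DataFrame(
        test_rows,
        columns=["stratum", "test", "n_go_class_I", "n_go_class_II",
                 "statistic", "p", "stars", "direction"],
    )
    return cv, tests


def run_imbalance(
    he_records: pd.DataFrame,
    wgd_records: pd.DataFrame,
    go_map: pd.DataFrame,
    params: PipelineParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """HE-vs-WGD comparison pooled over lines and generations.

    Within each dosage class (I/II) of GO terms, the per-GO CVs of every
    HE dosage group are tested against the 2:2 (PRV) CVs with two-sided
    rank-sum tests; the chi-square check compares the proportion of
    class I vs class II gene pairs between the HE and 2:2 datasets.
    """
    prv_cv = _response.group_response_variance(
        wgd_records, go_map, min_go_genes=params.min_go_genes,
        collapse_pairs=params.collapse_pairs,
    )
    test_rows, cv_frames = [], []
    if not prv_cv.empty:
        cv_frames.append(prv_cv.assign(dosage_group="2:2"))
    for go_class in ("I", "II"):
        ref = prv_cv.loc[prv_cv["go_class"] == go_class, "cv"].to_numpy()
        if ref.size == 0:
            log.warning("imbalance: no 2:2 GO terms in class %s; skipped",
                        go_class)
            continue
        groups = {}
        for dgroup in HE_DOSAGE_GROUPS:
            sub = he_records[he_records["dosage_class"] == dgroup]
            cvd = _response.group_response_variance(
                sub, go_map, min_go_genes=params.min_go_genes,
                collapse_pairs=params.collapse_pairs,
            )
            vals = cvd.loc[cvd["go_class"] == go_class, "cv"].to_numpy()
            if vals.size == 0:
                log.warning(
                    "imbalance: dosage group %s has no class %s GO terms; "
                    "comparison skipped", dgroup, go_class,
                )
                continue
            groups[dgroup] = vals
            cv_frames.append(
                cvd[cvd["go_class"] == go_class].assign(dosage_group=dgroup)
            )
        results = _stats.pairwise_wilcoxon(ref, groups, adjust=params.adjust)
        for dgroup, res in results.items():
            test_rows.append(
                (f"class {go_class}: {dgroup} vs 2:2", res.test_name,
                 res.group_sizes[0], res.group_sizes[1], res.statistic,
                 res.p_value, res.stars, res.direction or "")
            )

    # class-proportion check between the HE and 2:2 gene sets
    def _class_counts(records: pd.DataFrame) -> tuple[int, int]:
        hits = records[["pair_id"]].drop_duplicates().merge(
            go_map, on="pair_id"
        )[["pair_id", "go_class"]].drop_duplicates()
        return (int((hits["go_class"] == "I").sum()),
                int((hits["go_class"] == "II").sum()))

    he_i, he_ii = _class_counts(he_records)
    wgd_i, wgd_ii = _class_counts(wgd_records)
    try:
        chi = _stats.proportion_chisq([[he_i, he_ii], [wgd_i, wgd_ii]])
        test_rows.append(
            ("class proportions: HE vs 2:2", chi.test_name, he_i + he_ii,
             wgd_i + wgd_ii, chi.statistic, chi.p_value, chi.stars, "")
        )
    except ValidationError as exc:
        log.warning("imbalance: class-proportion chi-square skipped: %s", exc)

    tests = pd.DataFrame(
        test_rows,
        columns=["comparison", "test", "n1", "n2", "statistic", "p", "stars",
                 "direction"],
    )
    cv = (pd.concat(cv_frames, ignore_index=True) if cv_frames
          else pd.DataFrame(columns=_response.GO_CV_COLUMNS + ["dosage_group"]))
    return tests, cv


def run_pipeline(
    pairs: pd.DataFrame,
    depths: pd.DataFrame,
    expression: pd.DataFrame,
    parental: pd.DataFrame,
    sample_meta: pd.DataFrame,
    go_table: pd.DataFrame,
    *,
    ortholog_map: pd.DataFrame | None = None,
    params: PipelineParams | None = None,
    states: pd.DataFrame | None = None,
    outdir=None,
) -> PipelineResult:
    """Run dosage calling plus the HERV, PRV and imbalance analyses.

    ``states`` may be supplied to skip depth-based dosage calling (e.g.
    when dosage classes are known or precomputed); otherwise ``depths``
    is required. When ``outdir`` is given, all result tables, the HE
    segment BED and a JSON run manifest are written there; reruns with
    identical inputs and parameters are byte-identical.
    """
    params = params or PipelineParams()
    manifest: dict = {
        "version": __version__,
        "params": params.__dict__.copy(),
        "counts": {},
    }
    counts = manifest["counts"]
    counts["n_pairs"] = int(len(pairs))
    counts["n_samples"] = int(sample_meta["sample_id"].nunique())

    segments: list = []
    if states is None:
        if depths is None or len(depths) == 0:
            raise ValidationError(
                "0 pairs after dosage calling: depth table is empty and no "
                "precomputed states were provided"
            )
        counts["n_depth_rows"] = int(len(depths))
        states, segments = _dosage.call_dosage(
            pairs, depths, window=params.window, step=params.step,
            min_run=params.min_run,
        )
    counts["n_state_rows"] = int(len(states))
    counts["n_segments"] = len(segments)
    if len(states) == 0:
        raise ValidationError("0 pairs after dosage calling")

    exclusions = _dosage.flag_chromosome_scale(
        states, gene_majority=params.gene_majority,
        sample_majority=params.sample_majority,
    )
    counts["n_chrom_exclusions"] = len(exclusions)

    go_map = _response.transfer_go_annotations(pairs, go_table, ortholog_map)
    counts["n_go_terms"] = int(go_map["go_id"].nunique())
    counts["n_go_annotated_pairs"] = int(go_map["pair_id"].nunique())

    counts["n_expression_rows"] = int(len(expression))
    common = dict(
        min_sum_tpm=params.min_sum_tpm,
        bias_threshold_log2fc=params.bias_threshold_log2fc,
        pseudocount=params.pseudocount,
        exclusions=exclusions,
    )
    he_records = _response.build_response_records(
        expression, parental, states, sample_meta, "HE", **common
    )
    wgd_records = _response.build_response_records(
        expression, parental, states, sample_meta, "WGD", **common
    )
    counts["n_he_records"] = int(len(he_records))
    counts["n_wgd_records"] = int(len(wgd_records))

    strata = _strata(sample_meta)
    herv, herv_tests = _stratified_variance(
        he_records, go_map, params, strata, "HERV"
    )
    prv, prv_tests = _stratified_variance(
        wgd_records, go_map, params, strata, "PRV"
    )
    counts["n_herv_go_rows"] = int(len(herv))
    counts["n_prv_go_rows"] = int(len(prv))

    imbalance_tests, imbalance_cv = run_imbalance(
        he_records, wgd_records, go_map, params
    )

    result = PipelineResult(
        states=states, segments=segments, exclusions=exclusions,
        he_records=he_records, wgd_records=wgd_records,
        herv=herv, herv_tests=herv_tests, prv=prv, prv_tests=prv_tests,
        imbalance_tests=imbalance_tests, imbalance_cv=imbalance_cv,
        manifest=manifest,
    )
    if outdir is not None:
        write_results(result, outdir)
    return result


def write_results(result: PipelineResult, outdir) -> None:
    from . import io as _io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    states = result.states.copy()
    states.to_csv(out / "dosage_states.tsv", sep="\t", index=False)
    _io.write_segments_bed(result.segments, out / "he_segments.bed")
    _dosage.exclusions_frame(result.exclusions).to_csv(
        out / "exclusions.tsv", sep="\t", index=False
    )
    result.he_records.to_csv(out / "he_records.tsv", sep="\t", index=False)
    result.wgd_records.to_csv(out / "wgd_records.tsv", sep="\t", index=False)
    result.herv.to_csv(out / "herv_go_cv.tsv", sep="\t", index=False)
    result.herv_tests.to_csv(out / "herv_tests.tsv", sep="\t", index=False)
    result.prv.to_csv(out / "prv_go_cv.tsv", sep="\t", index=False)
    result.prv_tests.to_csv(out / "prv_tests.tsv", sep="\t", index=False)
    result.imbalance_tests.to_csv(
        out / "imbalance_tests.tsv", sep="\t", index=False
    )
    result.imbalance_cv.to_csv(out / "imbalance_cv.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
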