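"""Self-contained validation studies on synthetic data.

These functions wire the generator and the analysis together into the
package's standard verification experiments: planted-segment recovery of
the dosage caller, power and type-I behaviour of the HERV class
comparison, and the CV ordering across dosage groups that characterises
genomic imbalance. They are used by the test suite and by
``scripts/acceptance.py``, and are handy for sanity-checking parameter
changes.

Study dimensions are chosen to be informative at desk scale (a few
minutes on one core); the defaults of :class:`homeovar.simulate.SimConfig`
define the emulated study design itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import pandas as pd

from . import dosage as _dosage
from . import response as _response
from . import stats as _stats
from .simulate import (
    SimConfig,
    simulate_depths,
    simulate_dosage_mixture,
    simulate_genome,
    simulate_study,
    match_segments,
    false_segments,
)

_MOD = 2**31 - 1


def derive_seed(seed: int, *key: int) -> int:
    """A stable sub-seed below 2^31 derived from (seed, *key)."""
    out = int(seed) % _MOD
    for k in key:
        out = (out * 100_003 + int(k) + 1) % _MOD
    return out


def recovery_config(seed: int) -> SimConfig:
    """The planted-segment recovery fixture: 6 chromosome pairs of 2,000
    genes and 16 samples (8 lines at generations 1 and 10)."""
    return SimConfig(
        n_chromosome_pairs=6, pairs_per_chromosome=2000, n_lines=8,
        generations=(1, 10), n_go_per_class=60, genes_per_go=40,
        he_rate_per_generation=3.0, seed=derive_seed(seed, 1),
    )


@dataclass
class RecoveryResult:
    n_eligible: int
    n_recovered: int
    mean_boundary_error: float
    max_boundary_error: float
    n_false_noiseless: int
    n_called: int

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_eligible if self.n_eligible else 0.0


def segment_recovery_study(
    seed: int = 0, *, window: int = 170, min_run: int = 10
) -> RecoveryResult:
    """Recover planted HE segments from noisy and noiseless depth tracks.

    Eligible truth segments are those long enough to survive smoothing
    (length >= min_run + window); recovery requires the correct dosage
    class and both boundaries within window/2 pairs. False positives are
    counted on the noiseless variant as called segments further than one
    window away from any planted segment.
    """
    cfg = recovery_config(seed)
    study = simulate_study(cfg)
    _, called = _dosage.call_dosage(
        study.truth.pairs, study.depths, window=window, min_run=min_run
    )
    matches = match_segments(
        study.truth.segments, called,
        max_boundary_error=window // 2, min_length=min_run + window,
    )

    noiseless = replace(cfg, depth_noise=False)
    truth0 = simulate_genome(noiseless)
    depths0 = simulate_depths(truth0)
    _, called0 = _dosage.call_dosage(
        truth0.pairs, depths0, window=window, min_run=min_run
    )
    fp = false_segments(truth0.segments, called0, margin=window)

    recovered = matches["recovered"]
    errs = matches.loc[recovered, "boundary_error"]
    return RecoveryResult(
        n_eligible=int(len(matches)),
        n_recovered=int(recovered.sum()),
        mean_boundary_error=float(errs.mean()) if len(errs) else float("nan"),
        max_boundary_error=float(errs.max()) if len(errs) else float("nan"),
        n_false_noiseless=len(fp),
        n_called=len(called),
    )


# ---------------------------------------------------------------------------
# HERV class comparison: power and type-I error


_UNIFORM_HE = {"0:4": 0.25, "1:3": 0.25, "3:1": 0.25, "4:0": 0.25}


def herv_class_study_config(
    seed: int, *, kappa: float, n_go_per_class: int = 150,
    genes_per_go: int = 25,
) -> SimConfig:
    return SimConfig(
        n_go_per_class=n_go_per_class, genes_per_go=genes_per_go,
        constraint_factor=kappa,
        n_chromosome_pairs=1,
        pairs_per_chromosome=2 * n_go_per_class * genes_per_go,
        seed=seed,
    )


def herv_class_comparison_once(
    seed: int,
    *,
    kappa: float,
    class_probs: Mapping[str, float] | None = None,
    n_go_per_class: int = 150,
    genes_per_go: int = 25,
    min_go_genes: int = 20,
    n_samples: int = 16,
) -> _stats.TestResult:
    """One replicate: simulate HE responses and run the class comparison.

    The dosage mixture assigns every (pair, sample) an HE dosage class
    uniformly, so the HERV statistic is exercised directly without
    segment geometry. Observations are pooled over ``n_samples`` plants,
    as in the emulated study design (16 plants).
    """
    cfg = herv_class_study_config(
        seed, kappa=kappa, n_go_per_class=n_go_per_class,
        genes_per_go=genes_per_go,
    )
    study = simulate_dosage_mixture(cfg, class_probs or _UNIFORM_HE,
                                    n_samples=n_samples)
    records = _response.build_response_records(
        study.expression, study.parental, study.truth.states(),
        study.truth.sample_meta, "HE",
    )
    go_cv = _response.group_response_variance(
        records, study.truth.go_map, min_go_genes=min_go_genes
    )
    return _response.class_comparison(go_cv)


def herv_rejection_rate(
    seed: int,
    *,
    kappa: float,
    n_replicates: int,
    alpha: float = 0.05,
    **kwargs,
) -> float:
    """Fraction of replicates where the HERV class comparison rejects."""
    rejections = 0
    for i in range(n_replicates):
        res = herv_class_comparison_once(
            derive_seed(seed, 2, i), kappa=kappa, **kwargs
        )
        if res.p_value <= alpha:
            rejections += 1
    return rejections / n_replicates


# ---------------------------------------------------------------------------
# imbalance ordering across dosage groups


@dataclass
class ImbalanceResult:
    mean_cv: dict              # dosage group -> mean per-GO CV (pooled classes)
    tests: dict                # (go_class, dosage group) -> TestResult
    chisq: _stats.TestResult   # class proportions, HE vs 2:2 gene sets


def imbalance_ordering_study(
    seed: int = 0,
    *,
    n_samples: int = 16,
    n_go_per_class: int = 50,
    genes_per_go: int = 40,
    min_go_genes: int = 20,
) -> ImbalanceResult:
    """CV of the expression response by dosage group, HE groups vs 2:2.

    Dosage classes are mixed i.i.d. per (pair, sample) with the balanced
    class in the majority, mimicking pooling HE and balanced
    observations across lines and generations. Expected pattern under
    dosage-dependent expression with biased pairs: mean CV grows with
    dosage distance from 2:2, and every HE group is significantly more
    variable than the 2:2 (whole-genome duplication) response.
    """
    probs = {"2:2": 0.6, "0:4": 0.1, "1:3": 0.1, "3:1": 0.1, "4:0": 0.1}
    cfg = SimConfig(
        n_go_per_class=n_go_per_class, genes_per_go=genes_per_go,
        n_chromosome_pairs=1,
        pairs_per_chromosome=2 * n_go_per_class * genes_per_go,
        seed=derive_seed(seed, 3),
    )
    study = simulate_dosage_mixture(cfg, probs, n_samples=n_samples)
    states = study.truth.states()
    meta = study.truth.sample_meta
    he = _response.build_response_records(
        study.expression, study.parental, states, meta, "HE"
    )
    wgd = _response.build_response_records(
        study.expression, study.parental, states, meta, "WGD"
    )
    go_map = study.truth.go_map

    prv_cv = _response.group_response_variance(
        wgd, go_map, min_go_genes=min_go_genes
    )
    mean_cv = {"2:2": float(prv_cv["cv"].mean())}
    tests: dict = {}
    per_group_cv = {}
    for dgroup in ("0:4", "1:3", "3:1", "4:0"):
        sub = he[he["dosage_class"] == dgroup]
        cvd = _response.group_response_variance(
            sub, go_map, min_go_genes=min_go_genes
        )
        per_group_cv[dgroup] = cvd
        mean_cv[dgroup] = float(cvd["cv"].mean())
    for go_class in ("I", "II"):
        ref = prv_cv.loc[prv_cv["go_class"] == go_class, "cv"].to_numpy()
        for dgroup, cvd in per_group_cv.items():
            vals = cvd.loc[cvd["go_class"] == go_class, "cv"].to_numpy()
            tests[(go_class, dgroup)] = _stats.rank_sum_test(vals, ref)

    def _counts(records: pd.DataFrame) -> tuple[int, int]:
        hits = records[["pair_id"]].drop_duplicates().merge(go_map, on="pair_id")
        return (int((hits["go_class"] == "I").sum()),
                int((hits["go_class"] == "II").sum()))

    he_i, he_ii = _counts(he)
    wgd_i, wgd_ii = _counts(wgd)
    chisq = _stats.proportion_chisq([[he_i, he_ii], [wgd_i, wgd_ii]])
    return ImbalanceResult(mean_cv=mean_cv, tests=tests, chisq=chisq)
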