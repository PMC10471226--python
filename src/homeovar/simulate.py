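"""Synthetic allopolyploid fixtures with known truth.

The generator emulates the statistical structure the analysis assumes
for a resynthesized CCAA allotetraploid:

* a syntenic homoeolog pair map (~26,000 pairs on ordered chromosome
  pairs);
* HE segments planted per line that accumulate over generations — a
  generation-10 sample carries its line's earlier segments plus new
  ones — with dosage classes drawn from configurable weights and
  disjoint placement within a sample;
* WGS depth tracks: negative-binomial total depth per gene (Poisson as
  dispersion -> 0) allocated between homoeologs binomially, with a
  cross-mapping rate that leaks reads between subgenomes so that even a
  0:4 gene retains a little BnC-mapping depth;
* lognormal parental expression with a configurable fraction of
  biased pairs (|log2 fold change| above the bias threshold, sign
  weighted toward the dominant BnC subgenome);
* dosage-dependent polyploid expression: each homoeolog expresses its
  parental level scaled by copies/2 under multiplicative lognormal
  noise, with the noise SD multiplied by a constraint factor kappa for
  genes in dosage-sensitive (class II) GO terms — the generative analogue
  of a coordinated, constrained response;
* disjoint GO terms split evenly between class I and class II.

All randomness flows from one seed through named substreams, so adding
samples or stages never perturbs earlier draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .dosage import DOSAGE_CLASSES, HE_CLASSES, HESegment
from .errors import ValidationError

log = logging.getLogger(__name__)

COPY_BY_CLASS = {
    "0:4": (0, 4), "1:3": (1, 3), "2:2": (2, 2), "3:1": (3, 1), "4:0": (4, 0),
}


def _default_weights() -> dict[str, float]:
    # extreme (0:4/4:0) exchanges rarer than single-copy shifts
    return {"0:4": 0.15, "1:3": 0.35, "3:1": 0.35, "4:0": 0.15}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe the emulated study design: 6 isogenic lines
    sampled at generations 1, 5 and 10, ten homoeologous chromosome
    pairs totalling 26,000 syntenic pairs, and 300 GO terms of 40 genes
    split between dosage classes.
    """

    n_chromosome_pairs: int = 10
    pairs_per_chromosome: int = 2600
    n_lines: int = 6
    generations: tuple[int, ...] = (1, 5, 10)
    he_rate_per_generation: float = 3.0
    segment_min_length: int = 20
    segment_mean_length: float = 150.0
    segment_min_gap: int = 200
    dosage_class_weights: dict[str, float] = field(default_factory=_default_weights)
    depth_mean: float = 50.0
    depth_dispersion: float = 0.1
    depth_noise: bool = True
    cross_mapping_rate: float = 0.02
    expression_log_mean: float = 3.0
    expression_log_sd: float = 1.2
    biased_fraction: float = 0.15
    bias_c_share: float = 0.6
    bias_magnitude: float = 5.0
    response_noise_sd: float = 0.2
    constraint_factor: float = 0.7
    constraint_bias_scope: tuple[str, ...] = ("BnC", "BnA", "unbiased")
    n_go_per_class: int = 150
    genes_per_go: int = 40
    seed: int = 0

    def __post_init__(self):
        if self.n_chromosome_pairs < 1 or self.pairs_per_chromosome < 1:
            raise ValidationError("genome dimensions must be positive")
        if self.segment_min_length > self.pairs_per_chromosome:
            raise ValidationError(
                "segment_min_length exceeds chromosome length: infeasible"
            )
        if self.segment_mean_length < self.segment_min_length:
            raise ValidationError("segment_mean_length below segment_min_length")
        if not 0.0 <= self.cross_mapping_rate < 0.5:
            raise ValidationError("cross_mapping_rate must lie in [0, 0.5)")
        if not 0.0 < self.constraint_factor <= 1.0:
            raise ValidationError("constraint_factor must lie in (0, 1]")
        if not 0.0 <= self.biased_fraction <= 1.0:
            raise ValidationError("biased_fraction must lie in [0, 1]")
        if not 0.0 <= self.bias_c_share <= 1.0:
            raise ValidationError("bias_c_share must lie in [0, 1]")
        if self.bias_magnitude <= 3.5:
            raise ValidationError(
                "bias_magnitude must exceed the 3.5 log2FC bias cutoff"
            )
        if self.he_rate_per_generation < 0:
            raise ValidationError("he_rate_per_generation must be >= 0")
        if self.depth_dispersion < 0 or self.depth_mean <= 0:
            raise ValidationError("invalid depth parameters")
        if self.response_noise_sd < 0:
            raise ValidationError("response_noise_sd must be >= 0")
        bad = set(self.dosage_class_weights) - set(HE_CLASSES)
        if bad:
            raise ValidationError(f"unknown dosage classes in weights: {bad}")
        if any(w < 0 for w in self.dosage_class_weights.values()):
            raise ValidationError("dosage class weights must be >= 0")
        n_go_genes = 2 * self.n_go_per_class * self.genes_per_go
        if n_go_genes > self.n_chromosome_pairs * self.pairs_per_chromosome:
            raise ValidationError(
                f"GO terms need {n_go_genes} genes but the genome has only "
                f"{self.n_chromosome_pairs * self.pairs_per_chromosome} pairs"
            )
        unknown_scope = set(self.constraint_bias_scope) - {"BnC", "BnA", "unbiased"}
        if unknown_scope:
            raise ValidationError(f"unknown bias classes in scope: {unknown_scope}")

    @property
    def n_pairs(self) -> int:
        return self.n_chromosome_pairs * self.pairs_per_chromosome

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "generations" in raw:
            raw["generations"] = tuple(raw["generations"])
        if "constraint_bias_scope" in raw:
            raw["constraint_bias_scope"] = tuple(raw["constraint_bias_scope"])
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Ground truth backing a simulated study."""

    config: SimConfig
    pairs: pd.DataFrame            # pair map incl. chrom_pair
    go_map: pd.DataFrame           # pair_id, go_id, go_class
    bias: pd.DataFrame             # pair_id, bias_class
    sample_meta: pd.DataFrame      # sample_id, line_id, generation
    segments: list[HESegment]      # per-sample expanded planted segments
    copies: pd.DataFrame           # sample_id, pair_id, c_C, c_A

    def states(self) -> pd.DataFrame:
        """True dosage states in the same shape the caller produces."""
        df = self.copies.merge(
            self.pairs[["pair_id", "chrom_pair", "order_index"]], on="pair_id"
        )
        df["dosage_class"] = (
            df["c_C"].astype(str) + ":" + df["c_A"].astype(str)
        )
        return df[
            ["sample_id", "pair_id", "chrom_pair", "order_index", "dosage_class"]
        ]


@dataclass
class SimulatedStudy:
    """All inputs of one synthetic study plus its truth."""

    truth: SyntheticTruth
    depths: pd.DataFrame | None
    expression: pd.DataFrame
    parental: pd.DataFrame

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_pair_table(self.truth.pairs, out / "pairs.tsv")
        _io.write_sample_meta(self.truth.sample_meta, out / "samples.tsv")
        if self.depths is not None:
            _io.write_depth_table(self.depths, out / "depths.tsv")
        _io.write_expression_table(self.expression, out / "expression.tsv")
        _io.write_parental_table(self.parental, out / "parental.tsv")
        go = self.truth.go_map
        go.rename(columns={"pair_id": "gene_id"})[["gene_id", "go_id"]].to_csv(
            out / "go_genes.tsv", sep="\t", index=False
        )
        go[["go_id", "go_class"]].drop_duplicates().to_csv(
            out / "go_classes.tsv", sep="\t", index=False
        )
        self.truth.bias.to_csv(out / "truth_bias.tsv", sep="\t", index=False)
        self.truth.copies.to_csv(out / "truth_copies.tsv", sep="\t", index=False)
        _io.write_segments_bed(self.truth.segments, out / "truth_segments.bed")


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Named substream: a generator keyed by (seed, *key)."""
    return np.random.default_rng([int(seed)] + [int(k) for k in key])


# ---------------------------------------------------------------------------
# genome, GO and HE truth


def simulate_genome(config: SimConfig) -> SyntheticTruth:
    """Build the pair map, GO tables, bias classes and planted HE truth."""
    n_chrom = config.n_chromosome_pairs
    n_per = config.pairs_per_chromosome
    n_pairs = config.n_pairs

    chrom_idx = np.repeat(np.arange(n_chrom), n_per)
    order = np.tile(np.arange(n_per), n_chrom)
    pair_ids = np.array([f"pair{i:06d}" for i in range(n_pairs)])
    pairs = pd.DataFrame(
        {
            "pair_id": pair_ids,
            "gene_C": [f"BoC{c + 1}g{o:05d}" for c, o in zip(chrom_idx, order)],
            "gene_A": [f"BrA{c + 1}g{o:05d}" for c, o in zip(chrom_idx, order)],
            "chrom_C": [f"C{c + 1}" for c in chrom_idx],
            "chrom_A": [f"A{c + 1}" for c in chrom_idx],
            "order_index": order,
        }
    )
    pairs["chrom_pair"] = pairs["chrom_C"] + "/" + pairs["chrom_A"]

    # GO terms: disjoint gene sets, classes I then II
    rng_go = _rng(config.seed, 0)
    n_terms = 2 * config.n_go_per_class
    chosen = rng_go.choice(n_pairs, size=n_terms * config.genes_per_go,
                           replace=False)
    go_rows = []
    for t in range(n_terms):
        go_id = f"GO:{t + 1:07d}"
        go_class = "I" if t < config.n_go_per_class else "II"
        members = chosen[t * config.genes_per_go:(t + 1) * config.genes_per_go]
        for m in members:
            go_rows.append((pair_ids[m], go_id, go_class))
    go_map = pd.DataFrame(go_rows, columns=["pair_id", "go_id", "go_class"])

    # parental bias classes
    rng_bias = _rng(config.seed, 1)
    is_biased = rng_bias.random(n_pairs) < config.biased_fraction
    toward_c = rng_bias.random(n_pairs) < config.bias_c_share
    bias_class = np.where(
        is_biased, np.where(toward_c, "BnC", "BnA"), "unbiased"
    )
    bias = pd.DataFrame({"pair_id": pair_ids, "bias_class": bias_class})

    # sample metadata and planted segments with accumulation over generations
    gens = tuple(sorted(config.generations))
    meta_rows = []
    segments: list[HESegment] = []
    copies_frames = []
    class_names = list(config.dosage_class_weights)
    weights = np.array([config.dosage_class_weights[c] for c in class_names],
                       dtype=float)
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    weights = weights / weights.sum()
    mean_extra = config.segment_mean_length - config.segment_min_length
    p_geom = 1.0 / (1.0 + mean_extra) if mean_extra > 0 else 1.0
    chrom_pairs_order = [f"C{c + 1}/A{c + 1}" for c in range(n_chrom)]

    for line_i in range(config.n_lines):
        line_id = f"L{line_i + 1}"
        rng_line = _rng(config.seed, 2, line_i)
        line_segments: list[tuple[int, int, int, str, int]] = []
        # (chrom, start, end, class, generation planted)
        prev_gen = 0
        for gen in gens:
            sample_id = f"{line_id}_g{gen}"
            meta_rows.append((sample_id, line_id, gen))
            n_new = rng_line.poisson(
                config.he_rate_per_generation * (gen - prev_gen)
            )
            prev_gen = gen
            for _ in range(n_new):
                placed = False
                for _attempt in range(100):
                    chrom = int(rng_line.integers(n_chrom))
                    length = config.segment_min_length + (
                        int(rng_line.geometric(p_geom)) - 1 if p_geom < 1 else 0
                    )
                    if length > n_per:
                        continue
                    start = int(rng_line.integers(0, n_per - length + 1))
                    end = start + length
                    gap = config.segment_min_gap
                    clash = any(
                        c == chrom and start < e + gap and s - gap < end
                        for c, s, e, _cl, _g in line_segments
                    )
                    if clash:
                        continue
                    dclass = class_names[
                        int(rng_line.choice(len(class_names), p=weights))
                    ]
                    line_segments.append((chrom, start, end, dclass, gen))
                    placed = True
                    break
                if not placed:
                    log.warning(
                        "%s generation %d: could not place an HE segment "
                        "disjointly after 100 attempts; skipping", line_id, gen,
                    )
        # expand per-sample copies: a sample inherits all segments planted
        # at its generation or earlier
        for gen in gens:
            sample_id = f"{line_id}_g{gen}"
            c_C = np.full(n_pairs, 2, dtype=np.int8)
            c_A = np.full(n_pairs, 2, dtype=np.int8)
            for chrom, start, end, dclass, planted_gen in line_segments:
                if planted_gen > gen:
                    continue
                lo = chrom * n_per + start
                hi = chrom * n_per + end
                cc, ca = COPY_BY_CLASS[dclass]
                c_C[lo:hi] = cc
                c_A[lo:hi] = ca
                segments.append(
                    HESegment(
                        sample_id=sample_id,
                        chrom_pair=chrom_pairs_order[chrom],
                        start_index=start,
                        end_index=end,
                        dosage_class=dclass,
                    )
                )
            copies_frames.append(
                pd.DataFrame(
                    {"sample_id": sample_id, "pair_id": pair_ids,
                     "c_C": c_C, "c_A": c_A}
                )
            )

    sample_meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "line_id", "generation"]
    )
    copies = pd.concat(copies_frames, ignore_index=True)
    return SyntheticTruth(
        config=config, pairs=pairs, go_map=go_map, bias=bias,
        sample_meta=sample_meta, segments=segments, copies=copies,
    )


# ---------------------------------------------------------------------------
# depths


def simulate_depths(truth: SyntheticTruth) -> pd.DataFrame:
    """Draw per-gene WGS depths from the true copy numbers.

    Total depth per gene is negative binomial around ``depth_mean``
    (gamma-Poisson; Poisson when dispersion is 0); the BnC share is
    binomial with expectation (c_C + eps * c_A) / ((1 + eps)(c_C + c_A)),
    the cross-mapping rate eps leaking a fraction of each homoeolog's
    reads to the other subgenome. With ``depth_noise`` off, depths are
    the deterministic expectations (rounded), useful for exactness checks.
    """
    cfg = truth.config
    eps = cfg.cross_mapping_rate
    frames = []
    meta = truth.sample_meta.set_index("sample_id")
    for sample_id, grp in truth.copies.groupby("sample_id", sort=True):
        line_i = int(meta.loc[sample_id, "line_id"][1:]) - 1
        gen = int(meta.loc[sample_id, "generation"])
        rng = _rng(cfg.seed, 3, line_i, gen)
        c = grp["c_C"].to_numpy(dtype=float)
        a = grp["c_A"].to_numpy(dtype=float)
        total_copies = c + a
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(
                total_copies > 0,
                (c + eps * a) / np.where(total_copies > 0,
                                         (1.0 + eps) * total_copies, 1.0),
                0.0,
            )
        scale = total_copies / 4.0  # depth tracks total copy number
        mean = cfg.depth_mean * scale
        if cfg.depth_noise:
            if cfg.depth_dispersion > 0:
                lam = rng.gamma(
                    shape=1.0 / cfg.depth_dispersion,
                    scale=mean * cfg.depth_dispersion,
                )
            else:
                lam = mean
            total = rng.poisson(lam)
            depth_c = rng.binomial(total, p)
        else:
            total = np.round(mean).astype(np.int64)
            depth_c = np.round(total * p).astype(np.int64)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "pair_id": grp["pair_id"].to_numpy(),
                    "depth_C": depth_c,
                    "depth_A": total - depth_c,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# expression


def _parental_expression(truth: SyntheticTruth) -> pd.DataFrame:
    cfg = truth.config
    rng = _rng(cfg.seed, 4)
    n = len(truth.pairs)
    total = np.exp(rng.normal(cfg.expression_log_mean, cfg.expression_log_sd, n))
    ratio = 2.0 ** cfg.bias_magnitude
    bias = truth.bias["bias_class"].to_numpy()
    share_c = np.full(n, 0.5)
    share_c[bias == "BnC"] = ratio / (1.0 + ratio)
    share_c[bias == "BnA"] = 1.0 / (1.0 + ratio)
    return pd.DataFrame(
        {
            "pair_id": truth.pairs["pair_id"].to_numpy(),
            "tpm_oleracea": total * share_c,
            "tpm_rapa": total * (1.0 - share_c),
        }
    )


def _noise_sd_per_pair(truth: SyntheticTruth) -> np.ndarray:
    """Per-gene multiplicative noise SD, shrunk by kappa for constrained genes.

    The constraint applies to genes in dosage-sensitive (class II) GO
    terms whose parental bias class falls in ``constraint_bias_scope``.
    """
    cfg = truth.config
    sd = np.full(len(truth.pairs), cfg.response_noise_sd)
    class_ii = set(
        truth.go_map.loc[truth.go_map["go_class"] == "II", "pair_id"]
    )
    pair_ids = truth.pairs["pair_id"].to_numpy()
    bias = truth.bias.set_index("pair_id")["bias_class"]
    in_scope = np.isin(bias.loc[pair_ids].to_numpy(),
                       list(cfg.constraint_bias_scope))
    is_ii = np.fromiter((p in class_ii for p in pair_ids), dtype=bool,
                        count=len(pair_ids))
    sd[is_ii & in_scope] *= cfg.constraint_factor
    return sd


def simulate_expression(
    truth: SyntheticTruth,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate polyploid and parental TPM tables from the truth.

    Each homoeolog expresses its parental ortholog's level scaled by
    copies/2 (dosage-dependent response) times lognormal noise
    exp(N(0, sd)), sd shrunk by the constraint factor for constrained
    genes. Returns (polyploid expression, parental table).
    """
    cfg = truth.config
    parental = _parental_expression(truth)
    sd = _noise_sd_per_pair(truth)
    par = parental.set_index("pair_id")
    pair_ids = truth.pairs["pair_id"].to_numpy()
    ol = par["tpm_oleracea"].loc[pair_ids].to_numpy()
    ra = par["tpm_rapa"].loc[pair_ids].to_numpy()
    meta = truth.sample_meta.set_index("sample_id")

    frames = []
    for sample_id, grp in truth.copies.groupby("sample_id", sort=True):
        line_i = int(meta.loc[sample_id, "line_id"][1:]) - 1
        gen = int(meta.loc[sample_id, "generation"])
        rng = _rng(cfg.seed, 5, line_i, gen)
        # grp rows follow pair order within each sample by construction
        c = grp["c_C"].to_numpy(dtype=float)
        a = grp["c_A"].to_numpy(dtype=float)
        n = c.size
        noise_c = np.exp(rng.normal(0.0, 1.0, n) * sd)
        noise_a = np.exp(rng.normal(0.0, 1.0, n) * sd)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "pair_id": grp["pair_id"].to_numpy(),
                    "tpm_C": ol * (c / 2.0) * noise_c,
                    "tpm_A": ra * (a / 2.0) * noise_a,
                }
            )
        )
    return pd.concat(frames, ignore_index=True), parental


def simulate_study(config: SimConfig, outdir=None) -> SimulatedStudy:
    """Full fixture: genome truth, depth tracks and expression tables."""
    truth = simulate_genome(config)
    depths = simulate_depths(truth)
    expression, parental = simulate_expression(truth)
    study = SimulatedStudy(
        truth=truth, depths=depths, expression=expression, parental=parental
    )
    if outdir is not None:
        study.write(outdir)
    return study


# ---------------------------------------------------------------------------
# truth-aware evaluation


def match_segments(
    planted: Sequence[HESegment],
    called: Sequence[HESegment],
    *,
    max_boundary_error: int,
    min_length: int = 0,
) -> pd.DataFrame:
    """Score called HE segments against planted truth.

    A planted segment (restricted to those with at least ``min_length``
    genes) is recovered when a called segment in the same sample and
    chromosome pair has the same dosage class and both boundaries within
    ``max_boundary_error`` pairs of the truth. Returns one row per
    eligible planted segment with recovered flag and boundary errors.
    """
    by_key: dict[tuple[str, str], list[HESegment]] = {}
    for seg in called:
        by_key.setdefault((seg.sample_id, seg.chrom_pair), []).append(seg)
    rows = []
    for seg in planted:
        if seg.n_genes < min_length:
            continue
        best = None
        for cand in by_key.get((seg.sample_id, seg.chrom_pair), []):
            if cand.dosage_class != seg.dosage_class:
                continue
            err = max(abs(cand.start_index - seg.start_index),
                      abs(cand.end_index - seg.end_index))
            if best is None or err < best[0]:
                best = (err, cand)
        recovered = best is not None and best[0] <= max_boundary_error
        rows.append(
            (seg.sample_id, seg.chrom_pair, seg.start_index, seg.end_index,
             seg.dosage_class, seg.n_genes, recovered,
             np.nan if best is None else best[0])
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom_pair", "start_index", "end_index",
                 "dosage_class", "n_genes", "recovered", "boundary_error"],
    )


def false_segments(
    planted: Sequence[HESegment],
    called: Sequence[HESegment],
    *,
    margin: int,
) -> list[HESegment]:
    """Called segments lying entirely in balanced territory.

    A called segment is a false positive when it does not come within
    ``margin`` pairs of any planted segment of its sample and chromosome
    pair (window smoothing legitimately blurs class boundaries into the
    flanks of real events, so the neighbourhood of a planted segment is
    not counted as balanced).
    """
    by_key: dict[tuple[str, str], list[HESegment]] = {}
    for seg in planted:
        by_key.setdefault((seg.sample_id, seg.chrom_pair), []).append(seg)
    out = []
    for cand in called:
        near_truth = any(
            cand.start_index < p.end_index + margin
            and p.start_index - margin < cand.end_index
            for p in by_key.get((cand.sample_id, cand.chrom_pair), [])
        )
        if not near_truth:
            out.append(cand)
    return out


# ---------------------------------------------------------------------------
# segment-free dosage mixture (statistical studies)


def simulate_dosage_mixture(
    config: SimConfig,
    class_probs: Mapping[str, float],
    *,
    n_samples: int = 1,
) -> SimulatedStudy:
    """Segment-free variant: per-(pair, sample) dosage drawn i.i.d.

    For studies of the response statistics themselves (power, type-I
    error, CV ordering across dosage groups) segment geometry is
    irrelevant; this mode assigns every (pair, sample) a dosage class
    independently from ``class_probs`` (keys from the five dosage
    classes) and generates expression from the same dosage-dependent
    model. Depths are not simulated; use ``truth.states()`` as the
    dosage-state table.
    """
    bad = set(class_probs) - set(DOSAGE_CLASSES)
    if bad:
        raise ValidationError(f"unknown dosage classes: {bad}")
    probs = np.array([class_probs.get(c, 0.0) for c in DOSAGE_CLASSES], float)
    if probs.sum() <= 0 or (probs < 0).any():
        raise ValidationError("class probabilities must be non-negative, sum > 0")
    probs = probs / probs.sum()

    n_go_genes = 2 * config.n_go_per_class * config.genes_per_go
    cfg = replace(
        config,
        n_chromosome_pairs=1,
        pairs_per_chromosome=n_go_genes,
        n_lines=n_samples,
        generations=(1,),
        he_rate_per_generation=0.0,
    )
    truth = simulate_genome(cfg)
    # overwrite the all-balanced copies with the i.i.d. mixture
    frames = []
    pair_ids = truth.pairs["pair_id"].to_numpy()
    for s_i, sample_id in enumerate(truth.sample_meta["sample_id"]):
        rng = _rng(cfg.seed, 6, s_i)
        drawn = rng.choice(len(DOSAGE_CLASSES), size=len(pair_ids), p=probs)
        cc = np.array([COPY_BY_CLASS[DOSAGE_CLASSES[d]][0] for d in drawn],
                      dtype=np.int8)
        ca = np.array([COPY_BY_CLASS[DOSAGE_CLASSES[d]][1] for d in drawn],
                      dtype=np.int8)
        frames.append(
            pd.DataFrame(
                {"sample_id": sample_id, "pair_id": pair_ids,
                 "c_C": cc, "c_A": ca}
            )
        )
    truth.copies = pd.concat(frames, ignore_index=True)
    truth.segments = []
    expression, parental = simulate_expression(truth)
    return SimulatedStudy(
        truth=truth, depths=None, expression=expression, parental=parental
    )
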