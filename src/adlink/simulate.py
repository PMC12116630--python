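"""Synthetic two-stage digester experiments with planted ground truth.

The generator emulates the study design the pipeline targets: five
high-strength wastewater feeds (starch, protein, lipid, brewery, dairy),
each feeding a 1st-stage (acidogenic) and 2nd-stage (methanogenic) reactor
in series, sampled twice weekly from day 55 to day 185.  Each run plants:

* **core** genera per stage — present in every reactor of the stage and
  above the prevalence threshold;
* **unique** genera per (stage, feed) — present only under that feed;
* **correlates** per (stage, feed) — genera whose estimated absolute
  abundance tracks the pair's smoothed sCOD removal with a controlled
  Spearman correlation, planted through a Gaussian-copula rank link;
* **background** genera occupying several (never exactly one, never all)
  feeds per stage, independent of performance.

Per-feed removal follows a logistic ramp from roughly 40% at day 55 to a
feed-specific plateau (79% for lipid up to 96% for brewery) plus AR(1)
noise.  Total 16S copies/mL are log-normal and independent of removal.
Counts are negative-binomial around log-normal per-taxon expected
fractions of the sample's sequencing depth.  Every stochastic quantity
derives from a single seeded generator, so one seed gives bit-identical
output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    FEEDS,
    CountTable,
    Feed,
    PerformanceSeries,
    SampleRecord,
    Stage,
    write_count_table,
    write_metadata,
    write_scod,
)
from .performance import moving_average, removal_percent


class ConfigError(ValueError):
    """Generator configuration is internally inconsistent."""


#: Plateau removal percent per feed; lipid lowest, brewery highest.
DEFAULT_FEED_REMOVAL = {
    Feed.brewery: 96.0,
    Feed.dairy: 92.0,
    Feed.starch: 89.0,
    Feed.protein: 85.0,
    Feed.lipid: 79.0,
}

#: Influent sCOD (mg/L): ~8.8 g/L for the synthetic feeds, ~8 g/L otherwise.
DEFAULT_INFLUENT_SCOD = {
    Feed.starch: 8800.0,
    Feed.protein: 8800.0,
    Feed.lipid: 8800.0,
    Feed.brewery: 8000.0,
    Feed.dairy: 8000.0,
}

#: True qPCR standard curve used to emit Cq values (efficiency ~97.6%).
TRUE_CURVE_SLOPE = -3.38
TRUE_CURVE_INTERCEPT = 37.0


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic experiment; defaults are the study conditions."""

    n_feeds: int = 5
    n_background_taxa: int = 120
    n_core: int = 20                 # per stage
    n_unique_per_feed: int = 8       # per (stage, feed)
    n_correlates_per_feed: int = 1   # per (stage, feed)
    target_rho: float = 0.72
    n_total_taxa: int | None = None  # optional cap; planted taxa must fit
    day_start: int = 55
    day_end: int = 185
    depth_median: float = 12000.0
    depth_sigma_ln: float = 0.25
    copies_per_ml_median: float = 1.0e9
    copies_sigma_ln: float = 0.7
    removal_noise_sd: float = 2.0
    ar1_phi: float = 0.5
    scod_in_noise_sd: float = 150.0
    dropout: float = 0.0
    dip_day_130: bool = False
    correlate_sigma_ln: float = 0.8
    v_s: float = 1.5    # mL reactor sample extracted
    v_t: float = 100.0  # µL eluted DNA template
    feed_removal_mean: dict = field(default_factory=lambda: dict(DEFAULT_FEED_REMOVAL))
    seed: int = 0

    @property
    def feeds(self) -> tuple[Feed, ...]:
        return FEEDS[: self.n_feeds]

    def n_planted(self) -> int:
        per_stage = self.n_core + self.n_feeds * (
            self.n_unique_per_feed + self.n_correlates_per_feed
        )
        return 2 * per_stage

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        if not (1 <= self.n_feeds <= len(FEEDS)):
            raise ConfigError(f"n_feeds must be in [1, {len(FEEDS)}]")
        for name in ("n_background_taxa", "n_core", "n_unique_per_feed",
                     "n_correlates_per_feed"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if self.n_total_taxa is not None and self.n_planted() > self.n_total_taxa:
            raise ConfigError(
                f"{self.n_planted()} planted taxa exceed n_total_taxa="
                f"{self.n_total_taxa}"
            )


@dataclass
class SyntheticTruth:
    planted_core: dict[Stage, set[str]]
    planted_unique: dict[tuple[Stage, Feed], set[str]]
    planted_correlates: list[tuple[str, Stage, Feed, float]]
    feed_removal_mean: dict[Feed, float]
    seed: int

    def to_manifest(self) -> dict:
        return {
            "seed": self.seed,
            "planted_core": {s.value: sorted(v) for s, v in self.planted_core.items()},
            "planted_unique": {
                f"{s.value}:{f.value}": sorted(v)
                for (s, f), v in self.planted_unique.items()
            },
            "planted_correlates": [
                {"genus": g, "stage": s.value, "feed": f.value, "target_rho": rho}
                for g, s, f, rho in self.planted_correlates
            ],
            "feed_removal_mean": {f.value: m for f, m in self.feed_removal_mean.items()},
        }


@dataclass
class ExperimentBundle:
    counts: CountTable
    metadata: list[SampleRecord]
    qpcr: pd.DataFrame
    scod: list[PerformanceSeries]
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / "counts.tsv",
            "metadata": outdir / "metadata.tsv",
            "qpcr": outdir / "qpcr.tsv",
            "scod": outdir / "scod.tsv",
            "truth": outdir / "truth.json",
        }
        write_count_table(self.counts, paths["counts"])
        write_metadata(self.metadata, paths["metadata"])
        self.qpcr.to_csv(paths["qpcr"], sep="\t", index=False)
        write_scod(self.scod, paths["scod"])
        paths["truth"].write_text(
            json.dumps(self.truth.to_manifest(), indent=2, sort_keys=True) + "\n"
        )
        return paths


def sampling_days(day_start: int = 55, day_end: int = 185) -> list[int]:
    """Twice-weekly sampling dates: two visits per week, 3 days apart."""
    days = []
    week_start = day_start
    while week_start <= day_end:
        for offset in (0, 3):
            d = week_start + offset
            if d <= day_end:
                days.append(d)
        week_start += 7
    return days


def spearman_to_pearson_latent(rho_s: float) -> float:
    """Latent Gaussian correlation giving Spearman ``rho_s`` in a copula."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def plant_correlated_series(
    removal: Sequence[float],
    target_rho: float,
    rng: np.random.Generator,
    sigma_ln: float = 0.8,
    mu_ln: float = 0.0,
) -> np.ndarray:
    """Log-normal abundance series rank-linked to a removal series.

    Normal scores of the removal ranks are mixed with independent Gaussian
    noise at the latent correlation ``2 sin(pi * rho / 6)``, so the
    population Spearman correlation of the result with ``removal`` equals
    ``target_rho``; exponentiation preserves ranks.
    """
    removal = np.asarray(removal, dtype=float)
    n = removal.size
    ranks = stats.rankdata(removal)
    z_perf = stats.norm.ppf((ranks - 0.5) / n)
    r = spearman_to_pearson_latent(target_rho)
    eps = rng.standard_normal(n)
    z = r * z_perf + math.sqrt(max(0.0, 1.0 - r * r)) * eps
    return np.exp(mu_ln + sigma_ln * z)


def _logistic_ramp(day: np.ndarray, plateau: float) -> np.ndarray:
    """Removal ramp: ~40% at day 55 rising to the feed plateau by ~day 100."""
    return 40.0 + (plateau - 40.0) / (1.0 + np.exp(-(day - 70.0) / 6.0))


def _ar1(n: int, sd: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    if sd <= 0:
        return np.zeros(n)
    innov_sd = sd * math.sqrt(max(1e-12, 1.0 - phi * phi))
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = phi * out[i - 1] + rng.normal(0.0, innov_sd)
    return out


def _nb_counts(
    mean: np.ndarray, rng: np.random.Generator, size_param: float = 5.0
) -> np.ndarray:
    """Negative-binomial draws with the given means (gamma-Poisson mixture)."""
    mean = np.clip(np.asarray(mean, dtype=float), 1e-12, None)
    lam = rng.gamma(shape=size_param, scale=mean / size_param)
    return rng.poisson(lam)


def _reactor_id(feed: Feed, stage: Stage) -> str:
    tag = "s1" if stage is Stage.first else "s2"
    return f"{feed.value}_{tag}"


def generate_experiment(config: GeneratorConfig) -> ExperimentBundle:
    """Generate one complete synthetic experiment with recorded truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    feeds = config.feeds
    days = sampling_days(config.day_start, config.day_end)
    n_days = len(days)

    # --- performance series per reactor pair (one pair per feed) ---------
    scod_series: list[PerformanceSeries] = []
    smoothed_removal: dict[Feed, dict[int, float]] = {}
    day_arr = np.asarray(days, dtype=float)
    for feed in feeds:
        plateau = float(config.feed_removal_mean.get(feed, 88.0))
        removal = _logistic_ramp(day_arr, plateau)
        removal += _ar1(n_days, config.removal_noise_sd, config.ar1_phi, rng)
        if config.dip_day_130:
            removal -= 15.0 * np.exp(-(((day_arr - 130.0) / 6.0) ** 2))
        removal = np.clip(removal, 0.0, 99.9)
        scod_in = DEFAULT_INFLUENT_SCOD.get(feed, 8500.0) + rng.normal(
            0.0, config.scod_in_noise_sd, n_days
        )
        scod_in = np.clip(scod_in, 1000.0, None)
        scod_out = scod_in * (1.0 - removal / 100.0)
        records = [
            (int(d), float(i), float(o)) for d, i, o in zip(days, scod_in, scod_out)
        ]
        series = PerformanceSeries(pair_id=feed.value, records=records)
        realized = [(int(d), removal_percent(i, o)) for d, i, o in records]
        series.smoothed = moving_average(realized, window_days=5)
        scod_series.append(series)
        smoothed_removal[feed] = dict(series.smoothed)

    # --- metadata, depths, total copies ----------------------------------
    metadata: list[SampleRecord] = []
    for stage in (Stage.first, Stage.second):
        for feed in feeds:
            reactor = _reactor_id(feed, stage)
            for d in days:
                metadata.append(
                    SampleRecord(
                        sample_id=f"{reactor}_d{d:03d}",
                        reactor_id=reactor,
                        stage=stage,
                        feed=feed,
                        day=d,
                        v_s=config.v_s,
                        v_t=config.v_t,
                    )
                )
    sample_ids = [r.sample_id for r in metadata]
    n_samples = len(metadata)
    depths = np.exp(
        math.log(config.depth_median)
        + config.depth_sigma_ln * rng.standard_normal(n_samples)
    ).astype(np.int64)
    copies_per_ml = np.exp(
        math.log(config.copies_per_ml_median)
        + config.copies_sigma_ln * rng.standard_normal(n_samples)
    )
    col_of = {s: i for i, s in enumerate(sample_ids)}
    samples_of_reactor: dict[str, list[int]] = {}
    for i, rec in enumerate(metadata):
        samples_of_reactor.setdefault(rec.reactor_id, []).append(i)

    # --- taxon roster -----------------------------------------------------
    truth = SyntheticTruth(
        planted_core={Stage.first: set(), Stage.second: set()},
        planted_unique={},
        planted_correlates=[],
        feed_removal_mean={f: float(config.feed_removal_mean.get(f, 88.0)) for f in feeds},
        seed=config.seed,
    )
    taxa: list[str] = []
    core_names: dict[Stage, list[str]] = {}
    unique_names: dict[tuple[Stage, Feed], list[str]] = {}
    correlate_names: dict[tuple[Stage, Feed], list[str]] = {}
    for stage, tag in ((Stage.first, "s1"), (Stage.second, "s2")):
        core_names[stage] = [f"core_{tag}_{i:03d}" for i in range(config.n_core)]
        truth.planted_core[stage] = set(core_names[stage])
        taxa += core_names[stage]
        for feed in feeds:
            uniq = [
                f"uniq_{tag}_{feed.value}_{i:02d}"
                for i in range(config.n_unique_per_feed)
            ]
            unique_names[(stage, feed)] = uniq
            truth.planted_unique[(stage, feed)] = set(uniq)
            taxa += uniq
            corr = [
                f"corr_{tag}_{feed.value}_{i:02d}"
                for i in range(config.n_correlates_per_feed)
            ]
            correlate_names[(stage, feed)] = corr
            for g in corr:
                truth.planted_correlates.append((g, stage, feed, config.target_rho))
            taxa += corr
    n_background = config.n_background_taxa
    if config.n_total_taxa is not None:
        n_background = config.n_total_taxa - config.n_planted()
    bg_names = [f"bg_{i:04d}" for i in range(n_background)]
    taxa += bg_names
    counts = np.zeros((len(taxa), n_samples), dtype=np.int64)
    row_of = {t: i for i, t in enumerate(taxa)}
    rel_depth = depths / config.depth_median

    def nb_fill(row: int, cols: Sequence[int], base_fraction: float) -> None:
        mean = base_fraction * config.depth_median * rel_depth[list(cols)]
        counts[row, list(cols)] = _nb_counts(mean, rng)

    # core: one log-normal base fraction per taxon, all reactors of the stage
    for stage in (Stage.first, Stage.second):
        stage_cols = [i for i, r in enumerate(metadata) if r.stage == stage]
        for name in core_names[stage]:
            frac = float(np.exp(rng.normal(math.log(0.025), 0.5)))
            nb_fill(row_of[name], stage_cols, frac)

    # unique: only the assigned (stage, feed) reactor
    for (stage, feed), names in unique_names.items():
        cols = samples_of_reactor[_reactor_id(feed, stage)]
        for name in names:
            frac = float(np.exp(rng.normal(math.log(0.008), 0.7)))
            nb_fill(row_of[name], cols, frac)

    # background: per stage occupy 0 or 2..(n_feeds-1) feeds, never one/all
    occ_choices = [k for k in range(2, config.n_feeds)] or [0]
    for name in bg_names:
        row = row_of[name]
        frac = float(np.exp(rng.normal(math.log(0.004), 1.0)))
        occupied_any = False
        for stage in (Stage.first, Stage.second):
            k = int(rng.choice([0] + occ_choices))
            if k == 0 and not occupied_any and stage is Stage.second:
                k = occ_choices[0] if config.n_feeds >= 3 else 0
            if k == 0:
                continue
            occupied_any = True
            chosen = rng.choice(len(feeds), size=k, replace=False)
            for fi in chosen:
                cols = samples_of_reactor[_reactor_id(feeds[fi], stage)]
                nb_fill(row, cols, frac)
                _ensure_detection(counts, row, cols, rng)

    # correlates: background presence in all but one other feed of the stage
    for (stage, feed), names in correlate_names.items():
        others = [f for f in feeds if f is not feed]
        for j, name in enumerate(names):
            row = row_of[name]
            if len(others) >= 2:
                excluded = others[j % len(others)]
                frac = float(np.exp(rng.normal(math.log(0.004), 0.6)))
                for other in others:
                    if other is excluded:
                        continue
                    cols = samples_of_reactor[_reactor_id(other, stage)]
                    nb_fill(row, cols, frac)
                    _ensure_detection(counts, row, cols, rng)

    # detection guarantees for planted sets (per reactor of the stage)
    for stage in (Stage.first, Stage.second):
        for name in core_names[stage]:
            for feed in feeds:
                cols = samples_of_reactor[_reactor_id(feed, stage)]
                _ensure_detection(counts, row_of[name], cols, rng)
    for (stage, feed), names in unique_names.items():
        cols = samples_of_reactor[_reactor_id(feed, stage)]
        for name in names:
            _ensure_detection(counts, row_of[name], cols, rng)

    # --- plant correlates on the EAA scale via the copula rank link -------
    for (stage, feed), names in correlate_names.items():
        cols = samples_of_reactor[_reactor_id(feed, stage)]
        removal_vals = np.array(
            [smoothed_removal[feed][metadata[c].day] for c in cols]
        )
        for name in names:
            row = row_of[name]
            n_vec = copies_per_ml[cols]
            median_n = float(np.median(n_vec))
            mu_ln = math.log(0.01 * median_n)
            eaa_target = plant_correlated_series(
                removal_vals, config.target_rho, rng,
                sigma_ln=config.correlate_sigma_ln, mu_ln=mu_ln,
            )
            eaa_target = np.minimum(eaa_target, 0.5 * n_vec)
            s0 = counts[:, cols].sum(axis=0)  # column sums sans this taxon
            c = np.rint(eaa_target * s0 / (n_vec - eaa_target)).astype(np.int64)
            c = np.maximum(c, 1)
            if abs(config.target_rho) >= 0.999:
                c = _monotone_repair(
                    c, removal_vals, s0, n_vec, increasing=config.target_rho > 0
                )
            counts[row, cols] = c

    # --- detection dropout, then re-assert the planted guarantees ---------
    if config.dropout > 0:
        drop = rng.random(counts.shape) < config.dropout
        counts[drop] = 0
        for stage in (Stage.first, Stage.second):
            for name in core_names[stage]:
                for feed in feeds:
                    cols = samples_of_reactor[_reactor_id(feed, stage)]
                    _ensure_detection(counts, row_of[name], cols, rng)
        for (stage, feed), names in unique_names.items():
            cols = samples_of_reactor[_reactor_id(feed, stage)]
            for name in names:
                _ensure_detection(counts, row_of[name], cols, rng)

    # core prevalence guarantee: >= 50% of the stage's pooled samples
    for stage in (Stage.first, Stage.second):
        stage_cols = np.array([i for i, r in enumerate(metadata) if r.stage == stage])
        need = int(math.ceil(0.5 * stage_cols.size))
        for name in core_names[stage]:
            row = row_of[name]
            detected = counts[row, stage_cols] > 0
            deficit = need - int(detected.sum())
            if deficit > 0:
                zeros = stage_cols[~detected]
                bump = rng.choice(zeros.size, size=deficit, replace=False)
                counts[row, zeros[bump]] = 1

    # --- qPCR table --------------------------------------------------------
    copies_per_ul = copies_per_ml * config.v_s / config.v_t
    cq_true = (
        TRUE_CURVE_SLOPE * np.log10(np.clip(copies_per_ul, 1.0, None))
        + TRUE_CURVE_INTERCEPT
    )
    cq = cq_true[:, None] + rng.normal(0.0, 0.05, size=(n_samples, 2))
    qpcr = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cq_1": np.round(cq[:, 0], 4),
            "cq_2": np.round(cq[:, 1], 4),
            "copies_per_ul_template": copies_per_ul,
        }
    )

    count_table = CountTable(pd.DataFrame(counts, index=taxa, columns=sample_ids))
    return ExperimentBundle(
        counts=count_table, metadata=metadata, qpcr=qpcr,
        scod=scod_series, truth=truth,
    )


def _ensure_detection(
    counts: np.ndarray, row: int, cols: Sequence[int], rng: np.random.Generator
) -> None:
    """Guarantee at least one positive count for ``row`` among ``cols``."""
    cols = np.asarray(list(cols))
    if not (counts[row, cols] > 0).any():
        counts[row, cols[int(rng.integers(cols.size))]] = 1


def _monotone_repair(
    c: np.ndarray,
    removal: np.ndarray,
    s0: np.ndarray,
    n_vec: np.ndarray,
    increasing: bool,
) -> np.ndarray:
    """Adjust counts so realized EAA is strictly monotone in removal rank.

    Needed for |rho| = 1 plantings, where count rounding could otherwise
    introduce rank ties; realized EAA for count c is c*N/(S0 + c), which is
    increasing in c.
    """
    c = c.copy()
    order = np.argsort(removal if increasing else -removal)
    prev = -np.inf
    for idx in order:
        eaa = c[idx] * n_vec[idx] / (s0[idx] + c[idx])
        while eaa <= prev * (1 + 1e-9):
            c[idx] += 1
            eaa = c[idx] * n_vec[idx] / (s0[idx] + c[idx])
        prev = eaa
    return c


# ---------------------------------------------------------------------------
# Toy fixture: 8 taxa x 12 samples, hand-checkable membership
# ---------------------------------------------------------------------------

TOY_MANIFEST = {
    "core": {
        "first": ["g_core_both", "g_core_first", "g_ubiquitous"],
        "second": ["g_core_both", "g_second_only", "g_ubiquitous"],
    },
    # stage "second" has a single feed, so uniqueness is not assessable there
    "unique": {
        "first:starch": ["g_only_starch1", "g_ramp_starch"],
        "first:brewery": ["g_only_brewery1"],
        "second:starch": [],
    },
    "correlates": [
        {"genus": "g_ramp_starch", "stage": "first", "feed": "starch",
         "target_rho": 1.0}
    ],
}


def generate_toy_fixture() -> tuple[ExperimentBundle, dict]:
    """Fixed 8-taxon x 12-sample bundle (3 reactors, 2 feeds) with manifest."""
    reactors = [
        ("R1", Stage.first, Feed.starch),
        ("R2", Stage.first, Feed.brewery),
        ("R3", Stage.second, Feed.starch),
    ]
    days = [1, 2, 3, 4]
    metadata = [
        SampleRecord(
            sample_id=f"{rid}_d{d}", reactor_id=rid, stage=stage, feed=feed,
            day=d, v_s=1.5, v_t=100.0,
        )
        for rid, stage, feed in reactors
        for d in days
    ]
    sample_ids = [r.sample_id for r in metadata]
    rows = {
        #                R1: d1 d2 d3 d4   R2: d1 d2 d3 d4   R3: d1 d2 d3 d4
        "g_core_both":      [5, 6, 7, 8,      4, 4, 4, 4,      3, 3, 3, 3],
        "g_core_first":     [2, 0, 2, 0,      1, 0, 1, 0,      0, 0, 0, 0],
        "g_sparse":         [1, 0, 0, 0,      0, 0, 1, 0,      0, 0, 0, 0],
        "g_only_starch1":   [0, 9, 3, 0,      0, 0, 0, 0,      0, 0, 0, 0],
        "g_only_brewery1":  [0, 0, 0, 0,      7, 0, 2, 1,      0, 0, 0, 0],
        "g_second_only":    [0, 0, 0, 0,      0, 0, 0, 0,      5, 1, 0, 2],
        "g_ramp_starch":    [2, 4, 7, 11,     0, 0, 0, 0,      0, 0, 0, 0],
        "g_ubiquitous":     [1, 1, 1, 1,      1, 1, 1, 1,      1, 1, 1, 1],
    }
    counts = CountTable(
        pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    )
    qpcr = pd.DataFrame(
        {"sample_id": sample_ids, "copies_per_ul_template": [1.0e6] * len(sample_ids)}
    )
    scod = [
        PerformanceSeries(
            pair_id="starch",
            records=[(1, 8000, 4000), (2, 8000, 3000), (3, 8000, 2000), (4, 8000, 1000)],
        ),
        PerformanceSeries(
            pair_id="brewery",
            records=[(1, 8000, 800), (2, 8000, 800), (3, 8000, 800), (4, 8000, 800)],
        ),
    ]
    truth = SyntheticTruth(
        planted_core={
            Stage.first: set(TOY_MANIFEST["core"]["first"]),
            Stage.second: set(TOY_MANIFEST["core"]["second"]),
        },
        planted_unique={
            (Stage.first, Feed.starch): set(TOY_MANIFEST["unique"]["first:starch"]),
            (Stage.first, Feed.brewery): set(TOY_MANIFEST["unique"]["first:brewery"]),
            (Stage.second, Feed.starch): set(TOY_MANIFEST["unique"]["second:starch"]),
        },
        planted_correlates=[("g_ramp_starch", Stage.first, Feed.starch, 1.0)],
        feed_removal_mean={Feed.starch: 87.5, Feed.brewery: 90.0},
        seed=0,
    )
    bundle = ExperimentBundle(
        counts=counts, metadata=metadata, qpcr=qpcr, scod=scod, truth=truth
    )
    return bundle, TOY_MANIFEST
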