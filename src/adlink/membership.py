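"""Core / unique community membership.

Genera are partitioned per reactor stage on NON-rarefied counts:

* **core** — detected (count >= detection threshold) in at least one sample
  of *every* reactor of the stage, and detected in at least a prevalence
  fraction (default 50%) of the stage's samples.  The prevalence fraction
  is evaluated over the pooled samples of the stage by default; a
  per-reactor scope (threshold must hold within every reactor) is offered
  because the pooled reading is not the only defensible one.
* **unique** — detected under exactly one feed within the stage and in no
  sample of any other feed's reactor of that same stage.  Occurrences in
  the other stage are ignored: uniqueness is a within-stage notion.

A core genus is by construction present under every feed and therefore can
never be unique; the two sets are disjoint per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .datamodel import (
    CountTable,
    Feed,
    ResultRecord,
    SampleRecord,
    Stage,
    samples_by,
)

PrevalenceScope = Literal["pooled", "per-reactor"]


@dataclass
class MembershipResult:
    core: dict[Stage, set[str]] = field(default_factory=dict)
    unique: dict[tuple[Stage, Feed], set[str]] = field(default_factory=dict)
    prevalence: dict[tuple[Stage, str], float] = field(default_factory=dict)
    detection_threshold: int = 1

    def classify(self, genus: str, stage: Stage, feed: Feed) -> str:
        """Label a genus core / unique / other for a (stage, feed) context."""
        if genus in self.core.get(stage, set()):
            return "core"
        if genus in self.unique.get((stage, feed), set()):
            return "unique"
        return "other"


def _stage_samples(
    counts: CountTable, meta: Sequence[SampleRecord], stage: Stage
) -> list[SampleRecord]:
    recs = samples_by(meta, stage=stage)
    if not recs:
        raise ValueError(f"no samples for stage {stage.value!r}")
    present = set(counts.samples)
    return [r for r in recs if r.sample_id in present]


def find_core(
    counts: CountTable,
    meta: Sequence[SampleRecord],
    stage: Stage,
    prevalence_threshold: float = 0.5,
    detection_threshold: int = 1,
    prevalence_scope: PrevalenceScope = "pooled",
) -> set[str]:
    """Genera detected in every reactor of ``stage`` and prevalent enough."""
    if not isinstance(stage, Stage):
        raise ValueError(f"unknown stage {stage!r}")
    recs = _stage_samples(counts, meta, stage)
    detected = counts.data[[r.sample_id for r in recs]].to_numpy() >= detection_threshold

    reactors = sorted({r.reactor_id for r in recs})
    cols_of = {
        reac: [i for i, r in enumerate(recs) if r.reactor_id == reac]
        for reac in reactors
    }
    in_every_reactor = np.all(
        [detected[:, cols].any(axis=1) for cols in cols_of.values()], axis=0
    )
    if prevalence_scope == "pooled":
        prevalent = detected.mean(axis=1) >= prevalence_threshold
    elif prevalence_scope == "per-reactor":
        prevalent = np.all(
            [detected[:, cols].mean(axis=1) >= prevalence_threshold
             for cols in cols_of.values()],
            axis=0,
        )
    else:
        raise ValueError(f"unknown prevalence scope {prevalence_scope!r}")
    mask = in_every_reactor & prevalent
    return {t for t, m in zip(counts.taxa, mask) if m}


def stage_prevalence(
    counts: CountTable,
    meta: Sequence[SampleRecord],
    stage: Stage,
    detection_threshold: int = 1,
) -> dict[str, float]:
    """Fraction of the stage's pooled samples in which each genus is detected."""
    recs = _stage_samples(counts, meta, stage)
    detected = counts.data[[r.sample_id for r in recs]].to_numpy() >= detection_threshold
    return dict(zip(counts.taxa, detected.mean(axis=1)))


def find_unique(
    counts: CountTable,
    meta: Sequence[SampleRecord],
    stage: Stage,
    detection_threshold: int = 1,
) -> dict[Feed, set[str]]:
    """Genera detected under exactly one feed within ``stage``, keyed by feed."""
    if not isinstance(stage, Stage):
        raise ValueError(f"unknown stage {stage!r}")
    recs = _stage_samples(counts, meta, stage)
    detected = counts.data[[r.sample_id for r in recs]].to_numpy() >= detection_threshold

    feeds = sorted({r.feed for r in recs}, key=lambda f: f.value)
    if len(feeds) < 2:
        # uniqueness requires a cross-feed contrast; with one feed every
        # detected genus would be "unique" and collide with the core set
        return {feed: set() for feed in feeds}
    present_by_feed = {}
    for feed in feeds:
        cols = [i for i, r in enumerate(recs) if r.feed == feed]
        present_by_feed[feed] = detected[:, cols].any(axis=1)
    n_feeds_present = np.sum([present_by_feed[f] for f in feeds], axis=0)
    out: dict[Feed, set[str]] = {}
    for feed in feeds:
        mask = present_by_feed[feed] & (n_feeds_present == 1)
        out[feed] = {t for t, m in zip(counts.taxa, mask) if m}
    return out


def membership(
    counts: CountTable,
    meta: Sequence[SampleRecord],
    prevalence_threshold: float = 0.5,
    detection_threshold: int = 1,
    prevalence_scope: PrevalenceScope = "pooled",
) -> MembershipResult:
    """Core and unique sets for every stage present in the metadata."""
    result = MembershipResult(detection_threshold=detection_threshold)
    stages = sorted({r.stage for r in meta}, key=lambda s: s.value)
    for stage in stages:
        result.core[stage] = find_core(
            counts, meta, stage,
            prevalence_threshold=prevalence_threshold,
            detection_threshold=detection_threshold,
            prevalence_scope=prevalence_scope,
        )
        for feed, taxa in find_unique(
            counts, meta, stage, detection_threshold=detection_threshold
        ).items():
            result.unique[(stage, feed)] = taxa
        for genus, prev in stage_prevalence(
            counts, meta, stage, detection_threshold=detection_threshold
        ).items():
            result.prevalence[(stage, genus)] = prev
    return result


def membership_report(result: MembershipResult) -> list[ResultRecord]:
    """Per-stage core sizes and per-(stage, feed) unique sizes with members."""
    records = []
    for stage in sorted(result.core, key=lambda s: s.value):
        members = sorted(result.core[stage])
        records.append(
            ResultRecord(
                kind="core", stage=stage.value, feed="all",
                payload={"size": len(members), "members": ";".join(members)},
            )
        )
    for (stage, feed) in sorted(result.unique, key=lambda k: (k[0].value, k[1].value)):
        members = sorted(result.unique[(stage, feed)])
        records.append(
            ResultRecord(
                kind="unique", stage=stage.value, feed=feed.value,
                payload={"size": len(members), "members": ";".join(members)},
            )
        )
    return records
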