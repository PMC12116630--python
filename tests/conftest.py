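import numpy as np
import pandas as pd
import pytest

from adlink.datamodel import CountTable, Feed, SampleRecord, Stage
from adlink.simulate import GeneratorConfig, generate_experiment, generate_toy_fixture


@pytest.fixture(scope="session")
def toy():
    """Hand-checkable 8-taxon x 12-sample bundle plus its manifest."""
    bundle, manifest = generate_toy_fixture()
    return bundle, manifest


@pytest.fixture(scope="session")
def default_bundle():
    """One full synthetic experiment at the default study design."""
    return generate_experiment(GeneratorConfig(seed=20250921 % 2**31))


@pytest.fixture(scope="session")
def small_config():
    """Reduced experiment for fast end-to-end runs."""
    return GeneratorConfig(
        seed=5, day_end=97, n_background_taxa=40, n_core=8, n_unique_per_feed=3
    )


def random_count_table(rng, n_taxa=None, n_samples=None, max_count=20):
    n_taxa = n_taxa or int(rng.integers(2, 11))
    n_samples = n_samples or int(rng.integers(2, 21))
    counts = rng.integers(0, max_count, size=(n_taxa, n_samples))
    # avoid all-zero samples for distance/diversity statistics
    for j in range(n_samples):
        if counts[:, j].sum() == 0:
            counts[int(rng.integers(n_taxa)), j] = 1
    taxa = [f"t{i}" for i in range(n_taxa)]
    samples = [f"s{j}" for j in range(n_samples)]
    return CountTable(pd.DataFrame(counts, index=taxa, columns=samples))


def random_metadata(rng, sample_ids, n_feeds=3, stages=(Stage.first,)):
    """Random reactor layout: one reactor per (stage, feed), samples spread."""
    feeds = list(Feed)[:n_feeds]
    records = []
    for i, sid in enumerate(sample_ids):
        stage = stages[int(rng.integers(len(stages)))]
        feed = feeds[int(rng.integers(len(feeds)))]
        records.append(
            SampleRecord(
                sample_id=sid,
                reactor_id=f"{feed.value}_{stage.value}",
                stage=stage,
                feed=feed,
                day=i,
                v_s=1.5,
                v_t=100.0,
            )
        )
    return records
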