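import numpy as np
import pytest

from easleep.microstates import (
    assign_canonical_labels,
    backfit_peaks,
    compute_gfp,
    compute_metrics,
    find_gfp_peaks,
    modified_kmeans,
    two_level_templates,
)
from easleep.montage import standard_montage
from easleep.preprocess import microstate_prefilter
from easleep.synthgen import GroundTruth, default_truth, make_template_set, simulate_recordings


@pytest.fixture(scope="session")
def montage26():
    return standard_montage()


@pytest.fixture(scope="session")
def archetypes():
    return make_template_set()


@pytest.fixture(scope="session")
def hc_truth():
    return default_truth("hc", snr=2.0, seed=0)


@pytest.fixture(scope="session")
def uniform_truth(archetypes):
    """Equal dwell (70 ms) and uniform off-diagonal transitions."""
    p = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(p, 0.0)
    return GroundTruth(
        templates=archetypes,
        transition_matrix=p,
        mean_dwell_ms=np.full(4, 70.0),
        snr=2.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_closure(hc_truth):
    """A small generator->analyzer round trip shared by several tests.

    Four 60-s subjects at snr 2; returns the prefiltered recordings, the
    canonical group templates, and the per-subject metrics.
    """
    recs = simulate_recordings(hc_truth, 4, duration_s=60, rate=256, seed=10)
    prefiltered, subject_sets = [], []
    for i, rec in enumerate(recs):
        ms = microstate_prefilter(rec)
        gfp = compute_gfp(ms)
        peaks = find_gfp_peaks(gfp, ms.rate, 10.0)
        res = modified_kmeans(
            ms.data[:, peaks].T, k=4, restarts=20, seed=100 + i,
            weights=gfp[peaks], channel_names=ms.channel_names,
        )
        prefiltered.append(ms)
        subject_sets.append(res.templates)
    grp = two_level_templates(subject_sets, restarts=20, seed=5)
    labeled, match = assign_canonical_labels(grp.templates, hc_truth.templates)
    metrics = [compute_metrics(backfit_peaks(ms, labeled)) for ms in prefiltered]
    return {
        "truth": hc_truth,
        "recordings": prefiltered,
        "subject_sets": subject_sets,
        "templates": labeled,
        "match": match,
        "metrics": metrics,
    }
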