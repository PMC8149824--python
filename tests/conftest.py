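import numpy as np
import pandas as pd
import pytest

from wgdkit.loh import MarkerTrack


@pytest.fixture
def rng():
    return np.random.default_rng(20210525)


def make_track(positions, afs, baseline=0.5, chromosome="chr01", ploidy_context=2):
    """Marker track with explicit positions/allele frequencies (depth 100)."""
    return MarkerTrack(
        chromosome=chromosome,
        markers=pd.DataFrame(
            {
                "pos": np.asarray(positions, dtype=int),
                "af": np.asarray(afs, dtype=float),
                "total_depth": 100,
            }
        ),
        baseline_af=baseline,
        ploidy_context=ploidy_context,
    )


def brute_force_loh(track, deviation=0.15, af_tolerance=0.1, max_gap=300, min_markers=3):
    """Independent LOH segmentation oracle.

    Enumerates maximal stretches of deviating markers by explicit index
    walking, then splits each stretch at large gaps and at running-mean
    tolerance violations, keeping stretches of >= min_markers. Written
    without any shared code with wgdkit.loh.detect_loh.
    """
    pos = list(track.markers["pos"])
    af = list(track.markers["af"])
    n = len(pos)
    is_cand = [abs(a - track.baseline_af) > deviation for a in af]

    # maximal runs of consecutive candidate indices
    runs, i = [], 0
    while i < n:
        if is_cand[i]:
            j = i
            while j + 1 < n and is_cand[j + 1]:
                j += 1
            runs.append(list(range(i, j + 1)))
            i = j + 1
        else:
            i += 1

    segments = []
    for run in runs:
        block = [run[0]]
        for idx in run[1:]:
            mean_af = sum(af[k] for k in block) / len(block)
            if pos[idx] - pos[block[-1]] > max_gap or abs(af[idx] - mean_af) > af_tolerance + 1e-12:
                if len(block) >= min_markers:
                    segments.append(block)
                block = [idx]
            else:
                block.append(idx)
        if len(block) >= min_markers:
            segments.append(block)

    out = []
    for block in segments:
        seg_af = sum(af[k] for k in block) / len(block)
        out.append(
            {
                "start": pos[block[0]],
                "end": pos[block[-1]],
                "n_markers": len(block),
                "segment_af": seg_af,
                "retained_parent": "a" if seg_af > track.baseline_af else "b",
                "kind": "terminal"
                if block[0] == 0 or block[-1] == n - 1
                else "interstitial",
            }
        )
    return out


def random_track(rng, n_markers=None, with_loh_prob=0.5):
    """Small random marker track for oracle comparisons."""
    if n_markers is None:
        n_markers = int(rng.integers(1, 51))
    pos = np.sort(rng.choice(np.arange(1, 20_001), size=n_markers, replace=False))
    af = np.clip(rng.normal(0.5, 0.12, size=n_markers), 0.0, 1.0)
    if rng.random() < with_loh_prob and n_markers >= 3:
        i = int(rng.integers(0, n_markers - 2))
        length = int(rng.integers(3, min(10, n_markers - i) + 1))
        af[i : i + length] = np.clip(
            rng.normal(rng.choice([0.0, 1.0]), 0.04, size=length), 0.0, 1.0
        )
    return make_track(pos, af, baseline=float(np.mean(af)))
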