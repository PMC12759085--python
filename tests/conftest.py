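import numpy as np
import pytest

from morphlineage import TimepointSlice


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_slice(label, positions, clusters, prefix="c"):
    """Build a TimepointSlice from raw coordinates and cluster labels."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    ids = [f"{prefix}{label}_{i}" for i in range(len(positions))]
    return TimepointSlice(
        timepoint_label=label,
        cell_ids=ids,
        embedding=positions,
        cluster_labels=list(clusters),
    )


def brute_force_assignments(earlier, later, k):
    """Independent O(n^2) re-implementation of source-state assignment:
    full pairwise distances, python sorting, explicit tie rules."""
    out = {}
    for i, cid in enumerate(later.cell_ids):
        dists = []
        for j, eid in enumerate(earlier.cell_ids):
            d = float(np.linalg.norm(later.embedding[i] - earlier.embedding[j]))
            dists.append((d, str(eid), j))
        dists.sort()
        nn = dists[: min(k, len(dists))]
        labels = [earlier.cluster_labels[j] for _, _, j in nn]
        freq = {}
        for lab in labels:
            freq[lab] = freq.get(lab, 0) + 1
        top = max(freq.values())
        modal = [lab for lab, v in freq.items() if v == top]
        if len(modal) == 1:
            out[cid] = (modal[0], False)
        else:
            out[cid] = (labels[0], True)
    return out


def brute_force_graph(assignments, later, threshold):
    """Independent edge-fraction computation by direct counting."""
    cluster_of = dict(zip(later.cell_ids, later.cluster_labels))
    sizes = {}
    for lab in later.cluster_labels:
        sizes[lab] = sizes.get(lab, 0) + 1
    counts = {}
    for cid, (src, _) in assignments.items():
        key = (src, cluster_of[cid])
        counts[key] = counts.get(key, 0) + 1
    return {
        key: (n / sizes[key[1]], n / sizes[key[1]] > threshold)
        for key, n in counts.items()
    }
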