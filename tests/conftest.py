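import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from meibench.model import CallSet, MEICall, MEIClass, ReferenceMEI

CLASSES = (MEIClass.ALU, MEIClass.L1, MEIClass.SVA)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_match_instance(rng, n_refs=20, n_preds=30, span=20_000):
    """A random matching problem with overlapping windows, mixed TSD
    knowledge, mixed classes and off-target predictions."""
    refs = []
    for _ in range(n_refs):
        bp = int(rng.integers(200, span))
        cls = CLASSES[int(rng.integers(3))]
        if rng.random() < 0.5:
            tsd_len = int(rng.integers(5, 21))
            off = int(rng.integers(0, tsd_len))
            refs.append(ReferenceMEI("1", bp, cls, bp - off, bp - off + tsd_len - 1))
        else:
            refs.append(ReferenceMEI("1", bp, cls))
    preds = []
    for i in range(n_preds):
        if rng.random() < 0.7 and refs:
            ref = refs[int(rng.integers(len(refs)))]
            bp = max(1, ref.breakpoint + int(rng.integers(-70, 71)))
            cls = ref.mei_class if rng.random() < 0.8 else CLASSES[int(rng.integers(3))]
        else:
            bp = int(rng.integers(1, span))
            cls = CLASSES[int(rng.integers(3))]
        if rng.random() < 0.1:
            cls = MEIClass.UNKNOWN
        preds.append(MEICall(sample_id="S", chrom="1", breakpoint=bp, mei_class=cls,
                             split_reads=int(rng.integers(0, 9)),
                             discordant_pairs=int(rng.integers(0, 9)), tool="t"))
    return CallSet(calls=preds), refs


def brute_force_match(predictions, references, require_class=True,
                      tsd_pad=10, fallback_pad=50):
    """All-pairs nearest-reference assignment, no interval index.

    Independent re-statement of the matching rule used to check the
    indexed implementation pair-for-pair.
    """
    from meibench.model import MEIClass as MC, normalize_chrom

    pairs = []
    for i, call in enumerate(predictions):
        candidates = []
        for j, ref in enumerate(references):
            if normalize_chrom(call.chrom) != normalize_chrom(ref.chrom):
                continue
            if ref.tsd_start is not None:
                low, high = ref.tsd_start - tsd_pad, ref.tsd_end + tsd_pad
            else:
                low, high = ref.breakpoint - fallback_pad, ref.breakpoint + fallback_pad
            if not (low <= call.breakpoint <= high):
                continue
            if require_class and call.mei_class is not MC.UNKNOWN \
                    and call.mei_class is not ref.mei_class:
                continue
            candidates.append((abs(call.breakpoint - ref.breakpoint), ref.breakpoint, j))
        if candidates:
            pairs.append((i, min(candidates)[2]))
    return pairs


def union_find_merge(positions, tolerance):
    """Naive single-linkage clustering of breakpoints via union-find over
    all pairs within the tolerance."""
    n = len(positions)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= tolerance:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted(sorted(g) for g in groups.values())
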