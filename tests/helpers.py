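"""Independent oracles and small shared helpers for the test suite.

The oracles here deliberately avoid the implementation's own code paths:
the alignment oracle enumerates substring pairs with a memoized recursive
global-alignment score, and the rank-test oracle computes U from the
pairwise-comparison definition and p-values by explicit enumeration of
labelings.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from trnapanel.stats_report import PipelineConfig
from trnapanel.synthetic_data import PanelConfig

MATCH, MISMATCH, GAP = 1, -1, -2


def global_align_score(a: str, b: str) -> int:
    """Recursive (memoized) Needleman-Wunsch score of the full strings."""

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> int:
        if i == 0 and j == 0:
            return 0
        best = -(10**9)
        if i > 0 and j > 0:
            best = max(best, f(i - 1, j - 1) + (MATCH if a[i - 1] == b[j - 1] else MISMATCH))
        if i > 0:
            best = max(best, f(i - 1, j) + GAP)
        if j > 0:
            best = max(best, f(i, j - 1) + GAP)
        return best

    return f(len(a), len(b))


def brute_force_local_score(a: str, b: str) -> int:
    """Optimal local-alignment score by exhausting all substring pairs."""
    best = 0
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            for k in range(len(b)):
                for l in range(k + 1, len(b) + 1):
                    best = max(best, global_align_score(a[i:j], b[k:l]))
    return best


def mw_u_pairwise(x, y) -> float:
    """U for x by the pairwise-comparison definition (ties count 1/2)."""
    return float(sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y))


def mw_exact_oracle(x, y) -> tuple[float, float]:
    """(U, two-sided exact p) by full enumeration of pooled labelings."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = mw_u_pairwise(x, y)
    le = ge = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        u = mw_u_pairwise(xs, ys)
        total += 1
        le += u <= u_obs + 1e-9
        ge += u >= u_obs - 1e-9
    return u_obs, min(1.0, 2.0 * min(le, ge) / total)


def set_to_copy(oset, truth):
    """Map an emitted ortholog set to the unique ancestral copy it covers
    (None if the set mixes copies — which itself is a failure elsewhere)."""
    cids = {truth.locus_index.get((g, l)) for g, l in oset.members.items()}
    cids.discard(None)
    return cids.pop() if len(cids) == 1 else None


def recovered_pair_fraction(result, truth) -> float:
    """Fraction of true ortholog pairs placed in the same emitted set."""
    node_set = {}
    for s in result.sets:
        for g, l in s.members.items():
            node_set[(g, l)] = s.set_id
    hits = sum(
        1
        for a, b in truth.ortholog_pairs
        if node_set.get(a) is not None and node_set.get(a) == node_set.get(b)
    )
    return hits / len(truth.ortholog_pairs) if truth.ortholog_pairs else 1.0


def small_panel_config(seed: int, **overrides) -> PanelConfig:
    """A scaled-down panel for batch tests (structure, not size, matters)."""
    defaults = dict(
        n_strains=5,
        n_families=8,
        fragmentation_rate=0.2,
        oneway_noise_rate=0.1,
        paralog_trap_rate=0.1,
        seed=seed,
    )
    defaults.update(overrides)
    return PanelConfig(**defaults)


def pipeline_config(**overrides) -> PipelineConfig:
    return PipelineConfig(**overrides)
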