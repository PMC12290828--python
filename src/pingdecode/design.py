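"""Experimental design generation for the cued-recall ping experiment.

The experiment runs in blocks. In each block a set of verb-image pairs is
encoded once, then each pair is tested several times during recall. On 75% of
recall trials a high-contrast visual impulse (the "ping") is flashed at a
random latency inside one of three stimulus-onset-asynchrony (SOA) bins after
the retrieval cue; the remaining 25% receive no ping and serve as baseline.

A trial table is a plain :class:`pandas.DataFrame` with one row per trial and
the documented columns below; downstream modules attach it to epoched data.

Columns
-------
trial_id : int          unique, in presentation order
phase : str             'encoding' or 'recall'
block : int             1-based block index
pair_id : int           identity of the verb-image pair
condition : str         'early' | 'middle' | 'late' | 'none' (recall only)
ping_time_ms : float    ping onset relative to cue onset; NaN when no ping
label_top/mid/bot : str category labels of the paired image
image_id : int          leaf id in the stimulus hierarchy
lock : str              default time-lock of the row ('cue' or 'encoding_image')
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hierarchy import StimulusHierarchy, build_hierarchy

__all__ = [
    "CONDITIONS",
    "SOA_BINS_MS",
    "generate_design",
    "make_pseudo_pings",
    "validate_design",
]

CONDITIONS = ("early", "middle", "late", "none")

#: ping-onset bins (ms after retrieval-cue onset), uniform within each bin
SOA_BINS_MS = {
    "early": (500.0, 833.33),
    "middle": (833.34, 1116.67),
    "late": (1116.68, 1500.0),
}


def _order_without_immediate_repeats(pair_ids: np.ndarray, rng: np.random.Generator,
                                     max_tries: int = 2000) -> np.ndarray:
    """Return a permutation of indices such that consecutive pair_ids differ."""
    n = len(pair_ids)
    counts = pd.Series(pair_ids).value_counts()
    if counts.iloc[0] > (n + 1) // 2:
        raise ValueError(
            "no-immediate-repeat ordering infeasible: pair "
            f"{counts.index[0]} occurs {counts.iloc[0]} times in {n} trials"
        )
    idx = np.arange(n)
    for _ in range(max_tries):
        perm = rng.permutation(idx)
        if n < 2 or (pair_ids[perm][1:] != pair_ids[perm][:-1]).all():
            return perm
    # constructive fallback: repeatedly place a random pair different from the
    # previous one, preferring the most frequent remaining pair when forced
    remaining = pd.Series(pair_ids).groupby(pair_ids).indices
    remaining = {k: list(v) for k, v in remaining.items()}
    out: list[int] = []
    prev = None
    for _ in range(n):
        candidates = [k for k, v in remaining.items() if v and k != prev]
        if not candidates:
            raise ValueError("no-immediate-repeat ordering infeasible")
        # forced move: if one pair holds more than half of what's left it must
        # be placed now
        left = sum(len(v) for v in remaining.values())
        forced = [k for k in candidates if len(remaining[k]) > (left + 1) // 2]
        pick = forced[0] if forced else candidates[rng.integers(len(candidates))]
        out.append(remaining[pick].pop())
        prev = pick
    return np.asarray(out)


def generate_design(
    n_blocks: int = 8,
    n_pairs_per_block: int = 10,
    n_reps: int = 4,
    seed: int | np.random.Generator | None = None,
    hierarchy: StimulusHierarchy | None = None,
) -> pd.DataFrame:
    """Generate one participant's full trial table.

    Each block encodes ``n_pairs_per_block`` verb-image pairs (one encoding row
    per pair) and tests every pair ``n_reps`` times during recall. The
    repetitions of a pair are assigned evenly across the four ping conditions
    (early / middle / late / none), which, combined with a per-block 50/50
    object-scene split of the paired images, balances top-level categories
    within every condition. Ping onsets are drawn uniformly within their SOA
    bin. Within a block, recall order is randomised under the constraint that
    the same pair is never tested on two consecutive trials.

    Defaults give 8 x 10 x 4 = 320 recall trials (160 objects, 160 scenes,
    75% pinged) and 80 encoding rows.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_pairs_per_block % 2:
        raise ValueError(
            "n_pairs_per_block must be even: object/scene balance within each "
            f"condition is infeasible with {n_pairs_per_block} pairs and 2 "
            "top-level classes"
        )
    if n_reps % len(CONDITIONS):
        raise ValueError(
            f"n_reps={n_reps} not divisible by the {len(CONDITIONS)} ping "
            "conditions; supply an explicit allocation by choosing a multiple of 4"
        )
    hier = hierarchy if hierarchy is not None else build_hierarchy()
    per_class = n_blocks * n_pairs_per_block // 2
    for top, group in hier.leaves.groupby("top"):
        if per_class > len(group):
            raise ValueError(
                f"need {per_class} distinct '{top}' images but the hierarchy "
                f"holds only {len(group)}"
            )

    # sample pair images: per top class, without replacement across the whole
    # experiment; middle/bottom levels fall out fully randomly
    by_top = {
        top: group.sample(n=per_class, random_state=np.random.RandomState(rng.integers(2**31)))
        for top, group in hier.leaves.groupby("top")
    }
    tops = sorted(by_top)

    rows: list[dict] = []
    trial_id = 0
    pair_counter = 0
    reps_per_cond = n_reps // len(CONDITIONS)
    for block in range(1, n_blocks + 1):
        # this block's pairs: half per top class
        block_pairs = []
        for top in tops:
            chunk = by_top[top].iloc[
                (block - 1) * n_pairs_per_block // 2: block * n_pairs_per_block // 2
            ]
            for _, leaf in chunk.iterrows():
                block_pairs.append((pair_counter, leaf))
                pair_counter += 1
        order = rng.permutation(len(block_pairs))
        block_pairs = [block_pairs[i] for i in order]

        for pair_id, leaf in block_pairs:
            rows.append(
                {
                    "trial_id": trial_id,
                    "phase": "encoding",
                    "block": block,
                    "pair_id": pair_id,
                    "condition": "",
                    "ping_time_ms": np.nan,
                    "label_top": leaf["top"],
                    "label_mid": leaf["middle"],
                    "label_bot": leaf["bottom"],
                    "image_id": int(leaf["image_id"]),
                    "lock": "encoding_image",
                }
            )
            trial_id += 1

        # recall: every pair once per condition per repetition round
        recall = []
        for pair_id, leaf in block_pairs:
            for cond in CONDITIONS:
                for _ in range(reps_per_cond):
                    recall.append((pair_id, leaf, cond))
        pair_arr = np.asarray([p for p, _, _ in recall])
        perm = _order_without_immediate_repeats(pair_arr, rng)
        for i in perm:
            pair_id, leaf, cond = recall[i]
            if cond == "none":
                ping_time = np.nan
            else:
                lo, hi = SOA_BINS_MS[cond]
                ping_time = rng.uniform(lo, hi)
            rows.append(
                {
                    "trial_id": trial_id,
                    "phase": "recall",
                    "block": block,
                    "pair_id": pair_id,
                    "condition": cond,
                    "ping_time_ms": ping_time,
                    "label_top": leaf["top"],
                    "label_mid": leaf["middle"],
                    "label_bot": leaf["bottom"],
                    "image_id": int(leaf["image_id"]),
                    "lock": "cue",
                }
            )
            trial_id += 1

    design = pd.DataFrame(rows)
    validate_design(design)
    return design


def validate_design(design: pd.DataFrame) -> None:
    """Check the structural invariants of a trial table."""
    recall = design[design["phase"] == "recall"]
    ping = recall[recall["condition"] != "none"]
    if ping["ping_time_ms"].isna().any():
        raise ValueError("ping trials must carry a ping time")
    if recall.loc[recall["condition"] == "none", "ping_time_ms"].notna().any():
        raise ValueError("no-ping trials must not carry a ping time")
    for cond, (lo, hi) in SOA_BINS_MS.items():
        t = recall.loc[recall["condition"] == cond, "ping_time_ms"]
        if ((t < lo) | (t > hi)).any():
            raise ValueError(f"{cond} ping times outside [{lo}, {hi}] ms")
    for cond, group in recall.groupby("condition"):
        counts = group["label_top"].value_counts()
        if counts.nunique() > 1:
            raise ValueError(f"top-level labels unbalanced within condition {cond!r}")
    for _, block in recall.groupby("block"):
        pids = block.sort_values("trial_id")["pair_id"].to_numpy()
        if len(pids) > 1 and (pids[1:] == pids[:-1]).any():
            raise ValueError("a pair repeats on consecutive recall trials within a block")


def make_pseudo_pings(design: pd.DataFrame,
                      seed: int | np.random.Generator | None = None) -> pd.DataFrame:
    """Assign pseudo-ping times to the no-ping recall trials.

    Every no-ping trial receives a ``pseudo_ping_time_ms`` drawn with
    replacement from the pooled empirical ping times of this participant's
    pinged recall trials, providing a matched time-lock for baseline analyses.
    Ping trials keep their real ping time (copied into the same column so that
    ping-locked epoching can use one column for every trial).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = design.copy()
    recall = out["phase"] == "recall"
    is_ping = recall & (out["condition"] != "none")
    is_none = recall & (out["condition"] == "none")
    pool = out.loc[is_ping, "ping_time_ms"].to_numpy()
    if pool.size == 0:
        raise ValueError("cannot assign pseudo-pings: the design has no ping trials")
    if not is_none.any():
        raise ValueError("cannot assign pseudo-pings: the design has no no-ping trials")
    out["pseudo_ping_time_ms"] = np.nan
    out.loc[is_ping, "pseudo_ping_time_ms"] = out.loc[is_ping, "ping_time_ms"]
    out.loc[is_none, "pseudo_ping_time_ms"] = rng.choice(pool, size=int(is_none.sum()),
                                                         replace=True)
    return out
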