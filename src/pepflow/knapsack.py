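"""Exact mass-constrained sequence repair (multiple-choice knapsack).

Given per-position token log-probabilities and a residue-mass window, pick one
token per position maximizing the total log-probability subject to the total
residue mass lying inside the window. Solved exactly by dynamic programming
over residue masses discretized at 1e-3 Da, with the window inflated by one
bin per side so discretization can never produce a false infeasibility; the
returned sequence is verified against the exact (undiscretized) window.

The padding sentinel (mass 0) is a legal choice, which lets the solver shorten
the emitted peptide when that is what mass consistency requires.
"""

from __future__ import annotations

import numpy as np

__all__ = ["knapsack_repair", "brute_force_repair", "KnapsackInfeasible"]

DEFAULT_BIN_WIDTH = 1e-3
_CHUNK = 1 << 18  # mass bins processed per vectorized block


class KnapsackInfeasible(Exception):
    """No token sequence attains a total mass inside the window."""


def knapsack_repair(
    logprobs: np.ndarray,
    masses: np.ndarray,
    window: tuple[float, float],
    bin_width: float = DEFAULT_BIN_WIDTH,
    allowed: np.ndarray | None = None,
    top_q: int | None = None,
) -> np.ndarray:
    """Maximize sum_t logprobs[t, a_t] s.t. L <= sum_t masses[a_t] <= U.

    Parameters
    ----------
    logprobs : (T, V) per-position token log-probabilities.
    masses : (V,) residue masses in Da (sentinels 0).
    window : exact residue-mass window (L, U), water already excluded.
    allowed : optional (V,) bool mask of eligible tokens.
    top_q : optionally restrict each position to its ``top_q`` most probable
        eligible tokens (a speed/optimality trade-off; None = exact).

    Returns the (T,) array of chosen token ids, or raises
    :class:`KnapsackInfeasible`.
    """
    logprobs = np.asarray(logprobs, dtype=np.float64)
    masses = np.asarray(masses, dtype=np.float64)
    T, V = logprobs.shape
    L, U = window
    if not (0 <= L < U):
        raise ValueError(f"invalid residue-mass window [{L}, {U}]")
    if allowed is None:
        allowed = np.ones(V, dtype=bool)
    allowed = np.asarray(allowed, dtype=bool).copy()

    w_int = np.rint(masses / bin_width).astype(np.int64)
    lo_bin = max(int(np.floor(L / bin_width)) - 1, 0)
    hi_bin = int(np.ceil(U / bin_width)) + 1

    tokens = np.flatnonzero(allowed)
    max_w = int(w_int[tokens].max())
    if max_w * T < lo_bin:
        raise KnapsackInfeasible("window above the attainable mass range")

    # eligible tokens per position (optionally top-q by probability)
    per_pos_tokens: list[np.ndarray] = []
    for t in range(T):
        toks = tokens
        if top_q is not None and toks.size > top_q:
            order = np.argsort(logprobs[t, toks])[::-1][:top_q]
            toks = toks[np.sort(order)]
        per_pos_tokens.append(toks)

    # prefix reachability bounds (min token weight may be 0 via the sentinel)
    hi_cum = np.minimum(np.arange(1, T + 1, dtype=np.int64) * max_w, hi_bin)
    lo_cum = np.maximum(
        lo_bin - (T - 1 - np.arange(T, dtype=np.int64)) * max_w, 0
    )

    NEG = -np.inf
    prev_lo, prev_hi = 0, 0
    dp_prev = np.zeros(1)
    dp_store: list[np.ndarray] = []
    offsets: list[tuple[int, int]] = []
    buf = np.empty((tokens.size, _CHUNK))
    for t in range(T):
        lo_t, hi_t = int(lo_cum[t]), int(hi_cum[t])
        if lo_t > hi_t:
            raise KnapsackInfeasible("window unreachable at this length")
        size = hi_t - lo_t + 1
        dp = np.empty(size)
        toks = per_pos_tokens[t]
        # chunked vectorized relaxation over all eligible tokens
        for c_lo in range(0, size, _CHUNK):
            c_hi = min(c_lo + _CHUNK, size)
            block = buf[: toks.size, : c_hi - c_lo]
            for r, a in enumerate(toks):
                w = int(w_int[a])
                src_lo = lo_t + c_lo - w
                src_hi = lo_t + c_hi - w  # exclusive
                s_lo = max(src_lo, prev_lo)
                s_hi = min(src_hi, prev_hi + 1)
                if s_lo >= s_hi:
                    block[r, :] = NEG
                    continue
                d_lo = s_lo - src_lo
                d_hi = d_lo + (s_hi - s_lo)
                block[r, :d_lo] = NEG
                block[r, d_hi:] = NEG
                np.add(
                    dp_prev[s_lo - prev_lo : s_hi - prev_lo],
                    logprobs[t, a],
                    out=block[r, d_lo:d_hi],
                )
            block.max(axis=0, out=dp[c_lo:c_hi])
        dp_prev, prev_lo, prev_hi = dp, lo_t, hi_t
        dp_store.append(dp)
        offsets.append((lo_t, hi_t))

    final_lo = max(prev_lo, lo_bin)
    final_hi = min(prev_hi, hi_bin)
    if final_lo > final_hi:
        raise KnapsackInfeasible("no attainable mass inside the window")
    seg = dp_prev[final_lo - prev_lo : final_hi - prev_lo + 1]
    order = np.argsort(seg)[::-1]
    # try candidate end masses best-first until one passes the exact window
    for rank in order:
        if not np.isfinite(seg[rank]):
            break
        ids = _backtrack(
            final_lo + int(rank), dp_store, offsets, per_pos_tokens,
            logprobs, w_int,
        )
        if ids is None:
            continue
        exact = float(masses[ids].sum())
        if L <= exact <= U:
            return ids
    raise KnapsackInfeasible("no exactly feasible sequence inside the window")


def _backtrack(
    m: int,
    dp_store: list[np.ndarray],
    offsets: list[tuple[int, int]],
    per_pos_tokens: list[np.ndarray],
    logprobs: np.ndarray,
    w_int: np.ndarray,
) -> np.ndarray | None:
    """Reconstruct one optimal path ending at mass bin ``m`` by checking which
    token reproduces each dp value."""
    T = len(dp_store)
    ids = np.zeros(T, dtype=np.int64)
    for t in range(T - 1, -1, -1):
        lo_t, hi_t = offsets[t]
        target = dp_store[t][m - lo_t]
        prev_lo, prev_hi = (offsets[t - 1] if t > 0 else (0, 0))
        dp_prev = dp_store[t - 1] if t > 0 else np.zeros(1)
        found = False
        for a in per_pos_tokens[t]:
            pm = m - int(w_int[a])
            if prev_lo <= pm <= prev_hi:
                cand = dp_prev[pm - prev_lo] + logprobs[t, a]
                if np.isclose(cand, target, rtol=0.0, atol=1e-9):
                    ids[t] = a
                    m = pm
                    found = True
                    break
        if not found:
            return None
    return ids


def brute_force_repair(
    logprobs: np.ndarray,
    masses: np.ndarray,
    window: tuple[float, float],
    allowed: np.ndarray | None = None,
) -> tuple[np.ndarray | None, float]:
    """Exhaustive-enumeration reference solver for small instances.

    Returns (best ids or None, best score).
    """
    from itertools import product

    logprobs = np.asarray(logprobs, dtype=np.float64)
    masses = np.asarray(masses, dtype=np.float64)
    T, V = logprobs.shape
    L, U = window
    tokens = np.flatnonzero(
        np.ones(V, dtype=bool) if allowed is None else np.asarray(allowed)
    )
    best, best_score = None, -np.inf
    for combo in product(tokens, repeat=T):
        total_mass = masses[list(combo)].sum()
        if not (L <= total_mass <= U):
            continue
        score = sum(logprobs[t, a] for t, a in enumerate(combo))
        if score > best_score:
            best, best_score = np.array(combo), score
    return best, best_score
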