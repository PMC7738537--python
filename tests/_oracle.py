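"""Independent brute-force oracles used to check the vectorized caller."""

from __future__ import annotations

import numpy as np

from txends.calling import CallingParams


def brute_force_local_stats(
    counts: np.ndarray, params: CallingParams, topology: str = "linear"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Literal per-position loop over the ring window C(x).

    Independent of the prefix-sum implementation: windows are enumerated
    position by position and the mean/SD computed directly.
    Returns (mean, sd, z) with NaN where undefined.
    """
    counts = np.asarray(counts, dtype=np.float64)
    n = counts.size
    e, w = params.exclusion_radius, params.window_radius
    mean = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    z = np.full(n, np.nan)
    for x in range(1, n + 1):
        ys = []
        for y in range(max(1, x - w), min(n, x + w) + 1):
            d = abs(x - y)
            if topology == "circular":
                d = min(d, n - d)
            if e < d <= w:
                ys.append(y)
        if topology == "circular":
            # wrap-around arm beyond the linear neighbourhood
            for y in range(1, n + 1):
                d = min(abs(x - y), n - abs(x - y))
                if e < d <= w and y not in ys:
                    ys.append(y)
        if not ys:
            continue
        vals = counts[np.array(ys) - 1]
        m = float(vals.mean())
        var = float(((vals - m) ** 2).mean())
        if params.sd_mode == "sample":
            if vals.size < 2:
                continue
            var = var * vals.size / (vals.size - 1)
        s = var**0.5
        mean[x - 1] = m
        sd[x - 1] = s
        denom = max(s, params.sd_floor)
        if denom > 0:
            z[x - 1] = (counts[x - 1] - m) / denom
    return mean, sd, z


def assert_stats_equal(stats, oracle, atol: float = 1e-9) -> None:
    """NaN-aware comparison of LocalStats against the brute-force triple."""
    o_mean, o_sd, o_z = oracle
    for ours, ref, label in (
        (stats.local_mean, o_mean, "mean"),
        (stats.local_sd, o_sd, "sd"),
        (stats.z_raw, o_z, "z"),
    ):
        if not np.array_equal(np.isnan(ours), np.isnan(ref)):
            raise AssertionError(f"{label}: defined/undefined positions differ")
        ok = np.isnan(ours) | (np.abs(ours - ref) <= atol)
        if not ok.all():
            worst = np.nanmax(np.abs(ours - ref))
            raise AssertionError(f"{label}: max deviation {worst} exceeds {atol}")


def match_sites(calls, truth, tol: int = 1):
    """Greedy +-tol nt matching of called sites to truth (position, strand).

    Returns (n_matched_truth, n_true_positive_calls).  A truth site counts
    as recovered if any same-strand call lies within tol nt; a call counts
    as a true positive if it lies within tol nt of any truth site.
    """
    truth = list(truth)
    matched = 0
    for pos, strand in truth:
        if any(c.strand == strand and abs(c.position - pos) <= tol for c in calls):
            matched += 1
    tp_calls = sum(
        1
        for c in calls
        if any(s == c.strand and abs(c.position - p) <= tol for p, s in truth)
    )
    return matched, tp_calls
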