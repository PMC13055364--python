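"""Sliding-window recombination detection with permutation significance.

Three detectors operate on an aligned (recombinant, parent A, parent B)
triplet:

* ``maxchi`` — over the sites where the parents differ, the recombinant
  is coded as matching A or B; every candidate breakpoint contrasts the
  A-match counts in equal windows left and right of it with a 2x2
  chi-square, and the maximum statistic is tested by permuting site
  order (sites are exchangeable under the no-recombination null).
* ``chimaera`` — identical machinery on the sites where the recombinant
  differs from exactly one parent.
* ``bootscan_like`` — a sliding-window p-distance track from the
  recombinant to each candidate parent; switch points are argmin changes
  that persist for at least two windows. The test statistic is the
  largest window-wise advantage of any rival over the globally nearest
  candidate (zero when one parent leads in every window), and
  significance permutes the alignment columns and recomputes the
  windows — valid even though overlapping windows autocorrelate the
  track itself. A uniformly closest parent gives p = 1.

``scan_triplets`` enumerates all triplets, Bonferroni-corrects the
p-values over triplets x methods, and accepts an event only when at
least ``consensus_min`` detectors (default all three) fall below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DetectorResult", "RecombinationEvent", "maxchi", "chimaera",
           "bootscan_like", "scan_triplets"]


@dataclass
class DetectorResult:
    breakpoint: int | None     # alignment column
    statistic: float
    p_value: float


@dataclass
class RecombinationEvent:
    recombinant_id: str
    parent_ids: tuple[str, str]
    breakpoints: list[int]
    method_p: dict[str, float]        # Bonferroni-corrected
    n_supporting: int
    accepted: bool


def _as_array(*seqs: str) -> np.ndarray:
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        raise ValueError("sequences must be aligned to equal length")
    return np.array([np.frombuffer(s.encode(), dtype="S1") for s in seqs])


def _max_chi2(match: np.ndarray, window: int) -> tuple[float, int]:
    """Maximum 2x2 chi-square over all breakpoints with full windows on
    both sides; returns (statistic, breakpoint index into `match`)."""
    n = match.size
    if n < 2 * window:
        window = max(n // 2, 1)
    cs = np.concatenate([[0], np.cumsum(match)])
    ks = np.arange(window, n - window + 1)
    if ks.size == 0:
        return 0.0, n // 2
    left = cs[ks] - cs[ks - window]
    right = cs[ks + window] - cs[ks]
    a, b = left, window - left
    c, d = right, window - right
    tot = 2 * window
    row1, row2 = a + c, b + d
    # chi2 = N (ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)); (a+b)=(c+d)=window
    denom = window * window * row1 * row2
    chi2 = np.where(denom > 0,
                    tot * (a * d - b * c) ** 2.0 / np.maximum(denom, 1), 0.0)
    i = int(np.argmax(chi2))
    return float(chi2[i]), int(ks[i])


def _perm_pvalue(match: np.ndarray, window: int, observed: float,
                 n_permutations: int, rng: np.random.Generator) -> float:
    ge = 0
    for _ in range(n_permutations):
        stat, _ = _max_chi2(rng.permutation(match), window)
        if stat >= observed:
            ge += 1
    return (1 + ge) / (1 + n_permutations)


def _chi_detector(match: np.ndarray, site_cols: np.ndarray, window: int,
                  n_permutations: int, seed) -> DetectorResult:
    rng = np.random.default_rng(seed)
    obs, k = _max_chi2(match, window)
    p = _perm_pvalue(match, window, obs, n_permutations, rng)
    return DetectorResult(breakpoint=int(site_cols[k]) if site_cols.size
                          else None, statistic=obs, p_value=p)


def maxchi(recombinant: str, parent_a: str, parent_b: str,
           window: int = 15, n_permutations: int = 1000,
           seed=0) -> DetectorResult:
    """Maximum chi-square breakpoint test on parent-discriminating sites."""
    arr = _as_array(recombinant, parent_a, parent_b)
    rec, a, b = arr
    usable = (a != b) & (rec != b"-") & (a != b"-") & (b != b"-")
    informative = usable & ((rec == a) | (rec == b))
    cols = np.flatnonzero(informative)
    if cols.size == 0:
        raise ValueError("no variable sites between the parents")
    match = (rec[cols] == a[cols]).astype(np.int64)
    return _chi_detector(match, cols, window, n_permutations, seed)


def chimaera(recombinant: str, parent_a: str, parent_b: str,
             window: int = 15, n_permutations: int = 1000,
             seed=0) -> DetectorResult:
    """As maxchi, restricted to sites where the recombinant differs from
    exactly one parent (the parents themselves need not differ)."""
    arr = _as_array(recombinant, parent_a, parent_b)
    rec, a, b = arr
    nongap = (rec != b"-") & (a != b"-") & (b != b"-")
    informative = nongap & ((rec == a) ^ (rec == b))
    cols = np.flatnonzero(informative)
    if cols.size == 0:
        raise ValueError("no informative sites for chimaera")
    match = (rec[cols] == a[cols]).astype(np.int64)
    return _chi_detector(match, cols, window, n_permutations, seed)


def _longest_run(track: np.ndarray) -> int:
    if track.size == 0:
        return 0
    change = np.flatnonzero(track[1:] != track[:-1])
    bounds = np.concatenate([[-1], change, [track.size - 1]])
    return int(np.diff(bounds).max())


def bootscan_like(recombinant: str, candidates: dict[str, str],
                  window: int = 200, step: int = 50,
                  n_permutations: int = 1000, seed=0):
    """Nearest-parent track over sliding windows.

    Returns (DetectorResult, track) where track is a list of
    (window_start, nearest_candidate, distances dict). The breakpoint is
    the first persistent switch (argmin change lasting >= 2 windows).
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate parents")
    names = sorted(candidates)
    arr = _as_array(recombinant, *[candidates[n] for n in names])
    rec, rest = arr[0], arr[1:]
    n = rec.size
    if window > n:
        raise ValueError("window longer than alignment")
    rng = np.random.default_rng(seed)
    starts = np.arange(0, n - window + 1, step)
    diff = ((rest != rec[None, :]) & (rest != b"-")
            & (rec[None, :] != b"-")).astype(np.float64)
    valid = ((rest != b"-") & (rec[None, :] != b"-")).astype(np.float64)

    def window_dists(d, v):
        dc = np.concatenate([np.zeros((d.shape[0], 1)), np.cumsum(d, 1)], 1)
        vc = np.concatenate([np.zeros((v.shape[0], 1)), np.cumsum(v, 1)], 1)
        dw = dc[:, starts + window] - dc[:, starts]
        vw = vc[:, starts + window] - vc[:, starts]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(vw > 0, dw / np.maximum(vw, 1), np.inf)

    # global leader: smallest whole-alignment p-distance (permutation
    # invariant); the statistic is the largest window-wise advantage any
    # rival takes over the leader — 0 when the leader wins everywhere
    tot_v = valid.sum(axis=1)
    tot = np.where(tot_v > 0, diff.sum(axis=1) / np.maximum(tot_v, 1),
                   np.inf)
    leader = int(np.argmin(tot))

    def rival_advantage(dists):
        finite = np.isfinite(dists[leader])
        if not finite.any():
            return 0.0
        adv = dists[leader, finite] - dists[:, finite].min(axis=0)
        return float(adv.max())

    dists = window_dists(diff, valid)
    # hysteresis argmin track for switch-point reporting
    track = np.empty(len(starts), dtype=np.int64)
    prev = int(np.argmin(dists[:, 0]))
    for wi in range(len(starts)):
        if dists[prev, wi] > dists[:, wi].min():
            prev = int(np.argmin(dists[:, wi]))
        track[wi] = prev
    switches = []
    for wi in range(1, len(starts)):
        if track[wi] != track[wi - 1]:
            run = 1
            while wi + run < len(starts) and track[wi + run] == track[wi]:
                run += 1
            if run >= 2:
                switches.append(int(starts[wi]))
    obs = rival_advantage(dists)
    ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if rival_advantage(window_dists(diff[:, perm],
                                        valid[:, perm])) >= obs:
            ge += 1
    p = (1 + ge) / (1 + n_permutations)
    res = DetectorResult(breakpoint=switches[0] if switches else None,
                         statistic=float(obs), p_value=p)
    track_rows = [(int(s), names[t], dict(zip(names, dists[:, wi])))
                  for wi, (s, t) in enumerate(zip(starts, track))]
    return res, track_rows


def scan_triplets(sequences: dict[str, str], alpha: float = 0.05,
                  consensus_min: int = 3, window: int = 15,
                  bootscan_window: int = 200, bootscan_step: int = 50,
                  n_permutations: int = 1000, seed=0
                  ) -> list[RecombinationEvent]:
    """Run all three detectors on every (recombinant, parents) triplet.

    Duplicate sequences are collapsed before scanning. P-values are
    Bonferroni-corrected over triplets x methods; an event is accepted
    when at least ``consensus_min`` methods fall below ``alpha`` after
    correction.
    """
    uniq: dict[str, str] = {}
    seen: dict[str, str] = {}
    for name in sorted(sequences):
        s = sequences[name]
        if s not in seen:
            seen[s] = name
            uniq[name] = s
    names = sorted(uniq)
    if len(names) < 3:
        raise ValueError("need at least 3 distinct sequences")
    rng = np.random.default_rng(seed)
    triplets = []
    for r in names:
        others = [x for x in names if x != r]
        for i, a in enumerate(others):
            for b in others[i + 1:]:
                triplets.append((r, a, b))
    n_tests = len(triplets) * 3
    events = []
    for (r, a, b) in triplets:
        sub_seed = rng.integers(2 ** 31)
        try:
            m = maxchi(uniq[r], uniq[a], uniq[b], window=window,
                       n_permutations=n_permutations, seed=sub_seed)
            c = chimaera(uniq[r], uniq[a], uniq[b], window=window,
                         n_permutations=n_permutations, seed=sub_seed + 1)
            bs, _ = bootscan_like(uniq[r], {a: uniq[a], b: uniq[b]},
                                  window=bootscan_window,
                                  step=bootscan_step,
                                  n_permutations=n_permutations,
                                  seed=sub_seed + 2)
        except ValueError:
            continue
        corrected = {"maxchi": min(1.0, m.p_value * n_tests),
                     "chimaera": min(1.0, c.p_value * n_tests),
                     "bootscan": min(1.0, bs.p_value * n_tests)}
        supporting = sum(p < alpha for p in corrected.values())
        bps = sorted({bp for bp in (m.breakpoint, c.breakpoint,
                                    bs.breakpoint) if bp is not None})
        events.append(RecombinationEvent(
            recombinant_id=r, parent_ids=(a, b), breakpoints=bps,
            method_p=corrected, n_supporting=supporting,
            accepted=supporting >= consensus_min))
    return events
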