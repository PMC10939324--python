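"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own code paths: the peak counter
enumerates extrema sample-by-sample without run-compression, and the
ANOVA oracle builds every sum of squares from explicit Python loops over
marginal means.
"""

from __future__ import annotations

import numpy as np


def brute_force_peak_count(
    times: np.ndarray,
    speed: np.ndarray,
    cutoff: float = 0.020,
    min_sep: float = 0.150,
) -> int:
    """Velocity-peak count by exhaustive extremum enumeration.

    A sample ``i`` is a local maximum iff it strictly exceeds its
    immediate predecessor (so only the first sample of a plateau
    qualifies) and the nearest following sample with a different value
    is smaller (or no such sample exists).  The segment start acts as
    the initial minimum.  Each maximum is paired with the minimum of
    all samples since the previous maximum; it is a candidate when that
    rise strictly exceeds ``cutoff``.  Candidates are accepted in time
    order, each at least ``min_sep`` after the last accepted one.
    """
    n = len(speed)
    maxima: list[int] = []
    for i in range(1, n):
        if not speed[i] > speed[i - 1]:
            continue
        k = i + 1
        while k < n and speed[k] == speed[i]:
            k += 1
        if k == n or speed[k] < speed[i]:
            maxima.append(i)

    candidates: list[int] = []
    prev_max = 0
    for i in maxima:
        valley = min(speed[prev_max : i + 1])
        if speed[i] - valley > cutoff:
            candidates.append(i)
        prev_max = i

    accepted = 0
    t_last = -np.inf
    for i in candidates:
        if times[i] - t_last >= min_sep:
            accepted += 1
            t_last = times[i]
    return accepted


def rm_anova_oracle(y: np.ndarray) -> dict:
    """Two-way within-subject ANOVA by explicit loop-based decomposition.

    ``y[s, a, b]``: one observation per subject and cell.  Returns the
    sums of squares, F statistics and uncorrected p-values for the two
    main effects and the interaction, each tested against its
    subject-interaction error term.
    """
    from scipy.stats import f as fdist

    ns, na, nb = y.shape
    gm = sum(y[s, a, b] for s in range(ns) for a in range(na) for b in range(nb)) / (
        ns * na * nb
    )
    mean_a = [np.mean([y[s, a, b] for s in range(ns) for b in range(nb)]) for a in range(na)]
    mean_b = [np.mean([y[s, a, b] for s in range(ns) for a in range(na)]) for b in range(nb)]
    mean_s = [np.mean([y[s, a, b] for a in range(na) for b in range(nb)]) for s in range(ns)]
    mean_ab = [[np.mean([y[s, a, b] for s in range(ns)]) for b in range(nb)] for a in range(na)]
    mean_sa = [[np.mean([y[s, a, b] for b in range(nb)]) for a in range(na)] for s in range(ns)]
    mean_sb = [[np.mean([y[s, a, b] for a in range(na)]) for b in range(nb)] for s in range(ns)]

    ss_a = ns * nb * sum((m - gm) ** 2 for m in mean_a)
    ss_b = ns * na * sum((m - gm) ** 2 for m in mean_b)
    ss_s = na * nb * sum((m - gm) ** 2 for m in mean_s)
    ss_ab = ns * sum(
        (mean_ab[a][b] - mean_a[a] - mean_b[b] + gm) ** 2
        for a in range(na)
        for b in range(nb)
    )
    ss_sa = nb * sum(
        (mean_sa[s][a] - mean_s[s] - mean_a[a] + gm) ** 2
        for s in range(ns)
        for a in range(na)
    )
    ss_sb = na * sum(
        (mean_sb[s][b] - mean_s[s] - mean_b[b] + gm) ** 2
        for s in range(ns)
        for b in range(nb)
    )
    ss_total = sum(
        (y[s, a, b] - gm) ** 2 for s in range(ns) for a in range(na) for b in range(nb)
    )
    ss_res = ss_total - ss_a - ss_b - ss_s - ss_ab - ss_sa - ss_sb

    out = {"ss": {"A": ss_a, "B": ss_b, "A*B": ss_ab, "subject": ss_s,
                  "A*subject": ss_sa, "B*subject": ss_sb, "A*B*subject": ss_res,
                  "total": ss_total}}
    for name, ss_eff, ss_err, df1, df2 in (
        ("A", ss_a, ss_sa, na - 1, (na - 1) * (ns - 1)),
        ("B", ss_b, ss_sb, nb - 1, (nb - 1) * (ns - 1)),
        ("A*B", ss_ab, ss_res, (na - 1) * (nb - 1), (na - 1) * (nb - 1) * (ns - 1)),
    ):
        f = (ss_eff / df1) / (ss_err / df2)
        out[name] = {"F": f, "df1": df1, "df2": df2, "p": float(fdist.sf(f, df1, df2))}
    return out


def random_speed_profile(
    rng: np.random.Generator,
    sample_rate: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """A random multi-bump synthetic speed profile for oracle comparisons.

    0-5 bell-shaped bumps with amplitudes straddling the 20 mm/s cutoff
    and spacings straddling the 150 ms separation rule, optional value
    quantization (creating plateaus and exact ties), and optional smooth
    wander.
    """
    duration = rng.uniform(1.0, 4.0)
    n = int(duration * sample_rate) + 1
    t = np.arange(n) / sample_rate
    speed = np.zeros(n)
    n_bumps = int(rng.integers(0, 6))
    for _ in range(n_bumps):
        center = rng.uniform(0.05, duration - 0.05)
        width = rng.uniform(0.04, 0.6)
        amp = 10 ** rng.uniform(np.log10(0.004), np.log10(0.3))
        s = np.clip((t - center) / width + 0.5, 0.0, 1.0)
        speed += amp * 16 * (s * (1 - s)) ** 2
    if rng.random() < 0.3:
        wander = rng.normal(0, 0.01)
        speed += np.abs(wander) * (1 + np.sin(2 * np.pi * rng.uniform(0.2, 1.0) * t))
    if rng.random() < 0.3:
        speed = np.round(speed, 3)  # quantize: plateaus and exact ties
    return t, speed
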