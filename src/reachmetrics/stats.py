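"""Two-way repeated-measures statistics for the reaching features.

The design is fully within-subject: factor A is ball mode (2 levels),
factor B the analysis cell (baseline and one retention cell per trained
feedback modality, 4 levels), one value per participant per cell (the
cell mean of a kinematic feature, or a muscle's peak latency).

``rm_anova2`` computes the classical within-subject decomposition —
each effect tested against its own subject-by-effect interaction error
term — with Mauchly's sphericity test per effect and Greenhouse-Geisser
df correction applied when sphericity is rejected (``policy='auto'``).
Post-hoc paired t-tests use Bonferroni adjustment with the family equal
to the number of requested comparisons (default: baseline vs each
retention cell, m = 3, per ball mode).

``power_check`` is the parameter-recovery harness: it runs the full
simulate -> segment -> features -> ANOVA pipeline many times and
reports per-effect detection rates, usable both for type-I calibration
(no programmed effect) and for power under a programmed effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RmDataset",
    "EffectResult",
    "AnovaTable",
    "PosthocResult",
    "mauchly",
    "rm_anova2",
    "posthoc_bonferroni",
    "rm_dataset_from_summaries",
    "power_check",
]


@dataclass(frozen=True)
class RmDataset:
    """Balanced complete two-way within-subject dataset.

    ``data`` must hold one row per (subject, A level, B level) with
    columns named by ``subject``, ``factor_a``, ``factor_b``,
    ``value``.  Level order follows first appearance.
    """

    data: pd.DataFrame
    subject: str = "participant"
    factor_a: str = "ball_mode"
    factor_b: str = "cell"
    value: str = "value"

    def __post_init__(self) -> None:
        df = self.data
        for col in (self.subject, self.factor_a, self.factor_b, self.value):
            if col not in df.columns:
                raise ValueError(f"dataset lacks column {col!r}")
        counts = df.groupby([self.subject, self.factor_a, self.factor_b], sort=False)[
            self.value
        ].count()
        if (counts != 1).any():
            bad = counts[counts != 1]
            raise ValueError(
                f"design not balanced/complete: cell counts != 1 for "
                f"{list(bad.index[:5])}"
            )
        n_cells = len(self.a_levels) * len(self.b_levels)
        per_subj = df.groupby(self.subject, sort=False).size()
        if (per_subj != n_cells).any():
            raise ValueError("design not complete: missing cells for some subjects")

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.data[self.subject]))

    @property
    def a_levels(self) -> list:
        return list(pd.unique(self.data[self.factor_a]))

    @property
    def b_levels(self) -> list:
        return list(pd.unique(self.data[self.factor_b]))

    def cell_array(self) -> np.ndarray:
        """Values as ``Y[subject, a, b]`` in level order."""
        s_idx = {s: i for i, s in enumerate(self.subjects)}
        a_idx = {a: i for i, a in enumerate(self.a_levels)}
        b_idx = {b: i for i, b in enumerate(self.b_levels)}
        out = np.empty((len(s_idx), len(a_idx), len(b_idx)), dtype=float)
        for _, row in self.data.iterrows():
            out[s_idx[row[self.subject]], a_idx[row[self.factor_a]], b_idx[row[self.factor_b]]] = row[self.value]
        return out


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1, k) orthonormal contrast matrix (rows orthonormal, sum zero)."""
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, : i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1.0)
        helmert[i] /= np.linalg.norm(helmert[i])
    return helmert


def _effect_contrast_matrix(data: RmDataset, factor: str) -> np.ndarray:
    """Per-subject transformed scores for one effect's sphericity check."""
    y = data.cell_array()  # (s, a, b)
    n_a, n_b = y.shape[1], y.shape[2]
    if factor == "A":
        m = y.mean(axis=2)  # collapse over B
        c = _orthonormal_contrasts(n_a)
        return m @ c.T
    if factor == "B":
        m = y.mean(axis=1)
        c = _orthonormal_contrasts(n_b)
        return m @ c.T
    if factor == "A*B":
        c = np.kron(_orthonormal_contrasts(n_a), _orthonormal_contrasts(n_b))
        flat = y.reshape(y.shape[0], n_a * n_b)
        return flat @ c.T
    raise ValueError(f"factor must be 'A', 'B' or 'A*B', got {factor!r}")


def mauchly(data: RmDataset, factor: str) -> tuple[float, float, float]:
    """Mauchly's sphericity test and Greenhouse-Geisser epsilon.

    ``factor`` is ``'A'``, ``'B'`` or ``'A*B'``.  Returns
    ``(W, p_value, epsilon_GG)``.  A single-contrast effect (2 levels)
    is trivially spherical: ``(1.0, 1.0, 1.0)``.  When the contrast
    covariance is singular (too few subjects) the test statistic is
    undefined; ``W = nan, p = 1`` is returned with epsilon still
    computed from the eigenvalues.
    """
    t = _effect_contrast_matrix(data, factor)
    n, p = t.shape
    if p == 1:
        return 1.0, 1.0, 1.0
    if n < 2:
        raise ValueError("need at least 2 subjects")
    s = np.cov(t, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(s)
    eig = np.clip(eig, 0.0, None)
    eps = float(eig.sum() ** 2 / (p * np.sum(eig**2)))
    det = float(np.linalg.det(s))
    tr = float(np.trace(s))
    if n - 1 < p or det <= 0 or tr <= 0:
        return float("nan"), 1.0, eps
    w = det / (tr / p) ** p
    d = 1.0 - (2.0 * p**2 + p + 2.0) / (6.0 * p * (n - 1.0))
    chi2 = -(n - 1.0) * d * np.log(w)
    dof = p * (p + 1) / 2.0 - 1.0
    pval = float(sps.chi2.sf(chi2, dof))
    return float(w), pval, eps


@dataclass(frozen=True)
class EffectResult:
    """One row of the ANOVA table."""

    effect: str
    ss: float
    ss_error: float
    df: int
    df_error: int
    f: float
    p: float
    mauchly_w: float
    mauchly_p: float
    epsilon: float  # GG epsilon applied to the dfs (1 when uncorrected)


@dataclass(frozen=True)
class AnovaTable:
    """Two-way within-subject ANOVA result with the full SS accounting."""

    effects: tuple[EffectResult, ...]
    ss: Mapping[str, float] = field(default_factory=dict)

    def __getitem__(self, effect: str) -> EffectResult:
        for e in self.effects:
            if e.effect == effect:
                return e
        raise KeyError(effect)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.effects])


def _ss_decomposition(y: np.ndarray) -> dict[str, float]:
    """Explicit marginal-mean sums-of-squares decomposition of Y[s,a,b]."""
    n_s, n_a, n_b = y.shape
    gm = y.mean()
    a_m = y.mean(axis=(0, 2))
    b_m = y.mean(axis=(0, 1))
    s_m = y.mean(axis=(1, 2))
    ab_m = y.mean(axis=0)
    sa_m = y.mean(axis=2)
    sb_m = y.mean(axis=1)
    ss = {
        "A": n_s * n_b * float(np.sum((a_m - gm) ** 2)),
        "B": n_s * n_a * float(np.sum((b_m - gm) ** 2)),
        "subject": n_a * n_b * float(np.sum((s_m - gm) ** 2)),
        "A*B": n_s * float(np.sum((ab_m - a_m[:, None] - b_m[None, :] + gm) ** 2)),
        "A*subject": n_b * float(np.sum((sa_m - s_m[:, None] - a_m[None, :] + gm) ** 2)),
        "B*subject": n_a * float(np.sum((sb_m - s_m[:, None] - b_m[None, :] + gm) ** 2)),
        "total": float(np.sum((y - gm) ** 2)),
    }
    ss["A*B*subject"] = ss["total"] - sum(
        ss[k] for k in ("A", "B", "subject", "A*B", "A*subject", "B*subject")
    )
    return ss


def rm_anova2(data: RmDataset, sphericity_policy: str = "auto") -> AnovaTable:
    """Two-way repeated-measures ANOVA (both factors within-subject).

    Each effect is tested against its own interaction with subjects.
    ``sphericity_policy``:

    * ``'auto'`` — Greenhouse-Geisser df correction for an effect when
      Mauchly's test rejects at .05 for that effect;
    * ``'always'`` — GG correction for every multi-level effect;
    * ``'never'`` — uncorrected dfs throughout.
    """
    if sphericity_policy not in ("auto", "always", "never"):
        raise ValueError(f"unknown sphericity_policy {sphericity_policy!r}")
    y = data.cell_array()
    n_s, n_a, n_b = y.shape
    if n_s < 2:
        raise ValueError("need at least 2 subjects")
    ss = _ss_decomposition(y)
    layout = {
        "A": (n_a - 1, (n_a - 1) * (n_s - 1), "A*subject"),
        "B": (n_b - 1, (n_b - 1) * (n_s - 1), "B*subject"),
        "A*B": ((n_a - 1) * (n_b - 1), (n_a - 1) * (n_b - 1) * (n_s - 1), "A*B*subject"),
    }
    rows = []
    tol = 1e-12 * max(ss["total"], 1.0)  # numerically-zero SS threshold
    for effect, (df1, df2, err_key) in layout.items():
        if ss[effect] < tol:  # exactly null effect (up to round-off)
            f = 0.0
        elif ss[err_key] < tol:
            f = np.inf
        else:
            f = (ss[effect] / df1) / (ss[err_key] / df2)
        w, w_p, eps = mauchly(data, effect)
        apply_gg = sphericity_policy == "always" or (
            sphericity_policy == "auto" and w_p < 0.05
        )
        eps_used = eps if (apply_gg and df1 > 1) else 1.0
        p = float(sps.f.sf(f, df1 * eps_used, df2 * eps_used))
        rows.append(
            EffectResult(
                effect=effect,
                ss=ss[effect],
                ss_error=ss[err_key],
                df=df1,
                df_error=df2,
                f=float(f),
                p=p,
                mauchly_w=w,
                mauchly_p=w_p,
                epsilon=float(eps_used),
            )
        )
    return AnovaTable(effects=tuple(rows), ss=ss)


@dataclass(frozen=True)
class PosthocResult:
    """One Bonferroni-adjusted paired comparison."""

    comparison: tuple[str, str]
    split: str | None  # other-factor level the family was computed within
    n: int
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    m: int
    mean_diff: float


def posthoc_bonferroni(
    data: RmDataset,
    factor: str = "B",
    comparisons: Sequence[tuple[str, str]] | None = None,
    split_by_other: bool = True,
) -> list[PosthocResult]:
    """Paired t-tests on participant-matched cell values, Bonferroni-adjusted.

    Default comparisons: the first level of the factor (baseline)
    against each other level (m = len(comparisons)); computed within
    each level of the other factor when ``split_by_other`` (per ball
    mode), else on values averaged over the other factor.
    """
    if factor not in ("A", "B"):
        raise ValueError("factor must be 'A' or 'B'")
    y = data.cell_array()
    if y.shape[0] < 2:
        raise ValueError("need at least 2 participants for paired comparisons")
    levels = data.a_levels if factor == "A" else data.b_levels
    other_levels = data.b_levels if factor == "A" else data.a_levels
    if factor == "A":
        y = np.swapaxes(y, 1, 2)  # -> (s, other, factor)
    if comparisons is None:
        comparisons = [(levels[0], lv) for lv in levels[1:]]
    comparisons = [tuple(c) for c in comparisons]
    idx = {lv: i for i, lv in enumerate(levels)}
    for lv1, lv2 in comparisons:
        if lv1 not in idx or lv2 not in idx:
            raise ValueError(f"comparison ({lv1!r}, {lv2!r}) uses unknown levels")
    m = len(comparisons)
    splits: list[tuple[str | None, np.ndarray]]
    if split_by_other:
        splits = [(str(ol), y[:, j, :]) for j, ol in enumerate(other_levels)]
    else:
        splits = [(None, y.mean(axis=1))]
    out = []
    for split_label, mat in splits:
        for lv1, lv2 in comparisons:
            x1, x2 = mat[:, idx[lv1]], mat[:, idx[lv2]]
            res = sps.ttest_rel(x1, x2)
            out.append(
                PosthocResult(
                    comparison=(lv1, lv2),
                    split=split_label,
                    n=mat.shape[0],
                    t=float(res.statistic),
                    df=mat.shape[0] - 1,
                    p_raw=float(res.pvalue),
                    p_adjusted=min(1.0, m * float(res.pvalue)),
                    m=m,
                    mean_diff=float(np.mean(x1 - x2)),
                )
            )
    return out


# ---------------------------------------------------------------------------
# pipeline-level harnesses
# ---------------------------------------------------------------------------

def rm_dataset_from_summaries(
    summaries: pd.DataFrame, feature: str = "movement_time"
) -> RmDataset:
    """Build the ANOVA dataset for one feature from a summary table."""
    df = summaries[["participant", "ball_mode", "cell", feature]].rename(
        columns={feature: "value"}
    )
    # stable cell order: baseline first, then retention cells as they appear
    order = {"baseline": 0, "TV": 1, "TH": 2, "TM": 3}
    df = df.sort_values(
        ["participant", "ball_mode", "cell"],
        key=lambda col: col.map(order) if col.name == "cell" else col,
        kind="stable",
    ).reset_index(drop=True)
    return RmDataset(data=df)


def _simulate_feature_dataset(config, feature: str) -> RmDataset:
    """simulate -> segment -> features -> cell summaries, all participants."""
    from .kinematics import extract_features, summaries_to_frame, summarize
    from .segmentation import segment_session
    from .simulate import simulate_session

    all_summaries = []
    for p in range(config.n_participants):
        session = simulate_session(
            config, p, include_emg=False, include_training=False
        )
        segments = segment_session(session.trajectory, session.events)
        pairs = [(seg.trial, extract_features(seg)) for seg in segments]
        all_summaries.extend(summarize(pairs, participant=f"P{p:02d}"))
    return rm_dataset_from_summaries(summaries_to_frame(all_summaries), feature)


def power_check(
    config,
    n_replicates: int,
    alpha: float = 0.05,
    feature: str = "movement_time",
) -> dict[str, float]:
    """Detection rate per effect over full-pipeline Monte-Carlo replicates.

    Each replicate simulates a fresh cohort (seed offset by the
    replicate number), runs segmentation, feature extraction, cell
    summaries and the two-way RM-ANOVA on ``feature``, and records
    which effects reach ``p < alpha``.  With no programmed condition
    effect this calibrates the type-I error; with a programmed effect
    it estimates power.  Training blocks are skipped — they never enter
    inference.
    """
    hits = {"A": 0, "B": 0, "A*B": 0}
    for r in range(n_replicates):
        cfg = replace(config, seed=config.seed + 100_003 * r)
        data = _simulate_feature_dataset(cfg, feature)
        table = rm_anova2(data, sphericity_policy="auto")
        for effect in hits:
            if table[effect].p < alpha:
                hits[effect] += 1
    return {k: v / n_replicates for k, v in hits.items()}
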