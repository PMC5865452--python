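"""Group networks, interregional aggregation, main coupling direction and
the cohort-level statistical tests.

Group-level effective-connectivity (EC) networks keep an edge when it is
significant in strictly more than 75% of subjects (consensus rule); edge
strength is the mean over all subjects.  Subject-level interregional EC
averages the significant channel-pair strengths between each ordered pair
of the six regions (30 directed values).  The main coupling direction
(mCD) between two regions is decided by an exact two-sided binomial test
on the per-pair direction votes.  Contrasts use Kruskal-Wallis rank tests
(the strengths are not normally distributed), cognition correlations use
Pearson's r, and demographics use t / chi-square tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .bayesian import ConnectivityMatrix
from .errors import GroupingError
from .io_fnirs import ChannelLayout

CONSENSUS_FRACTION = 0.75


@dataclass
class GroupNetwork:
    """Group-averaged EC network with the >75% consensus mask."""

    mean_strengths: np.ndarray
    consensus_mask: np.ndarray
    n_subjects: int
    group: str = ""
    state: str = ""
    band: str = ""


@dataclass
class RegionNetwork:
    """Subject-level 6x6 directed interregional EC (NaN where no channel
    pair between the two regions was significant)."""

    ec: np.ndarray
    labels: tuple[str, ...]
    subject_id: str = ""
    state: str = ""
    band: str = ""


@dataclass
class McdResult:
    """Main coupling direction between two regions.

    direction: "r1->r2", "r2->r1" or "bidirectional"; defined=False when no
    significant channel pair exists between the regions.
    """

    region_1: str
    region_2: str
    direction: str
    p_value: float
    n_votes: int
    votes_r1_to_r2: int
    defined: bool = True


def group_network(
    matrices: list[ConnectivityMatrix],
    mean_over: str = "all",
    consensus: float = CONSENSUS_FRACTION,
) -> GroupNetwork:
    """Consensus EC network over one group/state/band.

    ``mean_over='all'`` averages every subject's strength for an edge
    (the adopted reading); ``'significant'`` averages only subjects where
    the edge passed the surrogate test.
    """
    if len(matrices) < 2:
        raise GroupingError("need at least 2 subjects for a group network")
    bands = {m.band for m in matrices}
    states = {m.state for m in matrices}
    if len(bands) > 1 or len(states) > 1:
        raise GroupingError(
            f"mixed inputs: bands={sorted(map(str, bands))}, "
            f"states={sorted(map(str, states))}"
        )
    s = np.stack([m.strengths for m in matrices])
    masks = np.stack([m.significant() for m in matrices])
    frac = masks.mean(axis=0)
    consensus_mask = frac > consensus  # strictly greater
    if mean_over == "all":
        mean = s.mean(axis=0)
    elif mean_over == "significant":
        with np.errstate(invalid="ignore"):
            mean = np.where(
                masks.any(axis=0),
                np.nansum(np.where(masks, s, 0.0), axis=0)
                / masks.sum(axis=0).clip(min=1),
                np.nan,
            )
    else:
        raise ValueError("mean_over must be 'all' or 'significant'")
    m0 = matrices[0]
    return GroupNetwork(
        mean_strengths=mean, consensus_mask=consensus_mask,
        n_subjects=len(matrices), state=m0.state or "", band=m0.band or "",
    )


def subject_region_ec(
    matrix: ConnectivityMatrix, layout: ChannelLayout
) -> RegionNetwork:
    """Mean strength of significant channel pairs per ordered region pair.

    With R regions this yields R*(R-1) directed aggregates (30 for the
    six-region montage); a value is NaN when no channel pair from the
    source region to the target region is significant.
    """
    mask = matrix.significant()
    labels = layout.labels
    R = len(labels)
    ec = np.full((R, R), np.nan)
    for a, ra in enumerate(labels):
        ia = layout.channels_in(ra) - 1
        for b, rb in enumerate(labels):
            if a == b:
                continue
            ib = layout.channels_in(rb) - 1
            sub_mask = mask[np.ix_(ia, ib)]
            if sub_mask.any():
                vals = matrix.strengths[np.ix_(ia, ib)][sub_mask]
                ec[a, b] = float(vals.mean())
    return RegionNetwork(
        ec=ec, labels=labels, subject_id=matrix.subject_id,
        state=matrix.state, band=matrix.band or "",
    )


def binomial_p_two_sided(k: int, n: int) -> float:
    """Exact two-sided binomial p against 0.5: double the smaller tail,
    capped at 1.  Matches the closed-form tail sum for any n."""
    if n == 0:
        return 1.0
    lo = min(k, n - k)
    tail = sum(comb(n, i) for i in range(0, lo + 1)) * 0.5**n
    return min(1.0, 2.0 * tail)


def mcd(
    matrices: ConnectivityMatrix | list[ConnectivityMatrix],
    layout: ChannelLayout,
    region_pair: tuple[str, str],
    alpha: float = 0.05,
) -> McdResult:
    """Main coupling direction between two regions.

    Every significant channel pair (i in r1, j in r2) casts one vote by
    comparing C_{i->j} with C_{j->i}; exact ties are dropped with a
    warning.  A list of matrices pools votes across subjects (the adopted
    group-level mode).  The vote split is tested against 0.5 with the
    exact two-sided binomial; a significant test gives a unidirectional
    label, otherwise the coupling is bidirectional.
    """
    import warnings

    if isinstance(matrices, ConnectivityMatrix):
        matrices = [matrices]
    r1, r2 = region_pair
    i1 = layout.channels_in(r1) - 1
    i2 = layout.channels_in(r2) - 1
    votes_12 = 0
    n_votes = 0
    for m in matrices:
        mask = m.significant()
        for a in i1:
            for b in i2:
                if not (mask[a, b] or mask[b, a]):
                    continue
                s_ab = m.strengths[a, b]
                s_ba = m.strengths[b, a]
                if s_ab == s_ba:
                    warnings.warn(
                        f"tied strengths for channels {a + 1},{b + 1}; "
                        "vote dropped", RuntimeWarning, stacklevel=2,
                    )
                    continue
                n_votes += 1
                if s_ab > s_ba:
                    votes_12 += 1
    if n_votes == 0:
        return McdResult(
            region_1=r1, region_2=r2, direction="undefined", p_value=np.nan,
            n_votes=0, votes_r1_to_r2=0, defined=False,
        )
    p = binomial_p_two_sided(votes_12, n_votes)
    if p < alpha:
        direction = "r1->r2" if votes_12 > n_votes - votes_12 else "r2->r1"
    else:
        direction = "bidirectional"
    return McdResult(
        region_1=r1, region_2=r2, direction=direction, p_value=p,
        n_votes=n_votes, votes_r1_to_r2=votes_12,
    )


def all_mcds(
    matrices: list[ConnectivityMatrix], layout: ChannelLayout,
    alpha: float = 0.05,
) -> list[McdResult]:
    """mCD for all unordered region pairs (15 for six regions)."""
    labels = layout.labels
    out = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            out.append(mcd(matrices, layout, (labels[a], labels[b]), alpha))
    return out


def _stack_ec(networks: list[RegionNetwork]) -> np.ndarray:
    return np.stack([n.ec for n in networks])


def contrast_ec(
    networks_a: list[RegionNetwork],
    networks_b: list[RegionNetwork],
    label_a: str = "a",
    label_b: str = "b",
) -> pd.DataFrame:
    """Kruskal-Wallis test per directed region pair between two samples of
    subject-level interregional EC values.

    Missing (NaN) subject values are dropped per connection; connections
    with fewer than 2 values on either side are skipped with a note.
    p-values are reported uncorrected, with a Benjamini-Hochberg column
    for transparency.
    """
    from statsmodels.stats.multitest import multipletests

    labels = networks_a[0].labels
    ec_a = _stack_ec(networks_a)
    ec_b = _stack_ec(networks_b)
    rows = []
    R = len(labels)
    for i in range(R):
        for j in range(R):
            if i == j:
                continue
            xa = ec_a[:, i, j]
            xb = ec_b[:, i, j]
            xa = xa[np.isfinite(xa)]
            xb = xb[np.isfinite(xb)]
            name = f"{labels[i]}->{labels[j]}"
            if len(xa) < 2 or len(xb) < 2:
                rows.append(
                    dict(connection=name, n_a=len(xa), n_b=len(xb),
                         H=np.nan, p=np.nan, direction="",
                         note="skipped: insufficient data")
                )
                continue
            if np.ptp(np.concatenate([xa, xb])) == 0:
                H, p = 0.0, 1.0
            else:
                H, p = stats.kruskal(xa, xb)
            direction = (
                f"{label_a}>{label_b}"
                if np.median(xa) > np.median(xb)
                else f"{label_b}>{label_a}"
            )
            rows.append(
                dict(connection=name, n_a=len(xa), n_b=len(xb),
                     H=float(H), p=float(p), direction=direction, note="")
            )
    df = pd.DataFrame(rows)
    tested = df["p"].notna()
    df["p_bh"] = np.nan
    if tested.any():
        df.loc[tested, "p_bh"] = multipletests(
            df.loc[tested, "p"], method="fdr_bh"
        )[1]
    return df


def correlate_mmse(
    networks: list[RegionNetwork], mmse: np.ndarray
) -> pd.DataFrame:
    """Pearson correlation of each directed interregional EC with MMSE.

    Connections with fewer than 4 complete observations or zero variance in
    either variable are flagged undefined.
    """
    labels = networks[0].labels
    ec = _stack_ec(networks)
    mmse = np.asarray(mmse, dtype=float)
    rows = []
    R = len(labels)
    for i in range(R):
        for j in range(R):
            if i == j:
                continue
            x = ec[:, i, j]
            ok = np.isfinite(x) & np.isfinite(mmse)
            name = f"{labels[i]}->{labels[j]}"
            if ok.sum() < 4 or np.ptp(x[ok]) == 0 or np.ptp(mmse[ok]) == 0:
                rows.append(
                    dict(connection=name, n=int(ok.sum()), r=np.nan,
                         p=np.nan, defined=False)
                )
                continue
            r, p = stats.pearsonr(x[ok], mmse[ok])
            rows.append(
                dict(connection=name, n=int(ok.sum()), r=float(r),
                     p=float(p), defined=True)
            )
    return pd.DataFrame(rows)


def demographics_tests(manifest: pd.DataFrame) -> pd.DataFrame:
    """Two-sample t-tests for age/BMI/MMSE and chi-square for sex counts."""
    groups = sorted(manifest["group"].unique())
    if len(groups) != 2:
        raise GroupingError("demographics tests need exactly 2 groups")
    a = manifest[manifest["group"] == groups[0]]
    b = manifest[manifest["group"] == groups[1]]
    rows = []
    for col in ("age", "bmi", "mmse"):
        if col not in manifest.columns:
            continue
        xa = pd.to_numeric(a[col], errors="coerce").dropna()
        xb = pd.to_numeric(b[col], errors="coerce").dropna()
        if len(xa) < 2 or len(xb) < 2:
            continue
        if np.ptp(np.concatenate([xa, xb])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=True)
        rows.append(
            dict(contrast=f"{col}: {groups[0]} vs {groups[1]}",
                 statistic=float(t), p=float(p), test="t")
        )
    if "sex" in manifest.columns:
        table = pd.crosstab(manifest["group"], manifest["sex"]).to_numpy()
        if table.shape == (2, 2) and table.sum() > 0:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            rows.append(
                dict(contrast=f"sex: {groups[0]} vs {groups[1]}",
                     statistic=float(chi2), p=float(p), test="chi2")
            )
    return pd.DataFrame(rows)
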