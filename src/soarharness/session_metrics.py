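"""Whole-flight-session summaries and the harness-difference test.

A flight session (one release-to-return flight) is summarised by its
duration, total distance, proportions of soaring and active flight, and
cumulative VeDBA. Harness types are compared per species with a pairwise
absolute-difference statistic: all between-harness absolute differences
ΔP = |P_i(backpack) − P_j(leg-loop)| of a session parameter P are tested
one-sidedly (Wilcoxon signed-rank) against the mean within-harness
absolute difference B, after subsampling the larger group to equalise
group sizes. A separate two-sided comparison serves validation data from
simultaneous double-tagging of a single bird.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gps_kinematics import GpsTrack

__all__ = [
    "FlightSession",
    "DeltaPResult",
    "summarize_session",
    "sessions_table",
    "equalize_groups",
    "delta_between",
    "baseline_within",
    "harness_comparison_test",
    "delta_p_test",
    "validation_compare",
]

#: session-level parameters entering the harness-difference test
SESSION_PARAMETERS = ("duration", "total_distance", "prop_soaring", "prop_active", "cumulative_vedba")


@dataclass(frozen=True)
class FlightSession:
    """Whole-flight summary of one session."""

    session_id: str
    individual_id: str
    species: str
    harness: str
    date: object
    duration: float            # s
    total_distance: float      # m, sum of step lengths
    prop_soaring: float        # fraction of movement-classified fixes soaring
    prop_active: float         # fraction of activity-classified fixes active
    cumulative_vedba: float    # g·s, sum of per-second mean VeDBA


@dataclass
class DeltaPResult:
    """Between- vs within-harness difference test for one species/parameter."""

    species: str
    parameter: str
    delta_samples: np.ndarray  # all |BP_i − LL_j| after equalisation
    baseline: float            # mean within-group absolute difference
    v_stat: float              # one-sided Wilcoxon signed-rank statistic
    p_value: float
    n_bp: int
    n_ll: int
    seed: int


def summarize_session(track: GpsTrack) -> FlightSession:
    """Summarise a classified 1 Hz track into a :class:`FlightSession`."""
    df = track.data
    meta = track.meta
    t = df["time"]
    duration = (t.iloc[-1] - t.iloc[0]).total_seconds() if len(df) > 1 else 0.0
    total_distance = float(np.nansum(df["step_length"].to_numpy(dtype=float))) if "step_length" in df else 0.0

    movement = df["movement"].dropna() if "movement" in df else pd.Series(dtype=object)
    activity = df["activity"].dropna() if "activity" in df else pd.Series(dtype=object)
    if len(movement) == 0 or len(activity) == 0:
        warnings.warn(f"session {meta.get('session_id')}: no classified fixes; proportions missing",
                      stacklevel=2)
    prop_soaring = float((movement == "soaring").mean()) if len(movement) else float("nan")
    prop_active = float((activity == "active").mean()) if len(activity) else float("nan")
    cumulative_vedba = float(df["vedba"].dropna().sum()) if "vedba" in df else float("nan")

    return FlightSession(
        session_id=meta.get("session_id", ""),
        individual_id=meta.get("individual_id", ""),
        species=meta.get("species", ""),
        harness=meta.get("harness", ""),
        date=meta.get("date"),
        duration=duration,
        total_distance=total_distance,
        prop_soaring=prop_soaring,
        prop_active=prop_active,
        cumulative_vedba=cumulative_vedba,
    )


def sessions_table(sessions) -> pd.DataFrame:
    """Stack :class:`FlightSession` records into the session-level table."""
    return pd.DataFrame([s.__dict__ for s in sessions])


def equalize_groups(bp, ll, seed: int = 0):
    """Subsample the larger group (without replacement) to the smaller's size."""
    bp = np.asarray(bp, dtype=float)
    ll = np.asarray(ll, dtype=float)
    if bp.size == 0 or ll.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    n = min(bp.size, ll.size)
    if bp.size > n:
        bp = rng.choice(bp, size=n, replace=False)
    elif ll.size > n:
        ll = rng.choice(ll, size=n, replace=False)
    return bp, ll


def delta_between(bp, ll) -> np.ndarray:
    """All between-group absolute differences |BP_i − LL_j|, row-major."""
    bp = np.asarray(bp, dtype=float)
    ll = np.asarray(ll, dtype=float)
    return np.abs(bp[:, None] - ll[None, :]).ravel()


def baseline_within(bp, ll) -> float:
    """Mean absolute difference within groups, pooled over both harnesses.

    A group of size one contributes no pairs; if neither group has at
    least two members the baseline is undefined and a ``ValueError`` is
    raised.
    """
    pairs = []
    for grp in (np.asarray(bp, dtype=float), np.asarray(ll, dtype=float)):
        if grp.size >= 2:
            i, j = np.triu_indices(grp.size, k=1)
            pairs.append(np.abs(grp[i] - grp[j]))
    if not pairs:
        raise ValueError("baseline undefined: both groups have fewer than 2 members")
    return float(np.mean(np.concatenate(pairs)))


def harness_comparison_test(delta_samples, baseline: float):
    """One-sided Wilcoxon signed-rank test of ΔP against the baseline.

    Tests whether the between-harness absolute differences are *greater*
    than the (fixed) mean within-harness difference B, i.e. a signed-rank
    test on ΔP − B with alternative 'greater'. Returns ``(v_stat, p)``.
    """
    d = np.asarray(delta_samples, dtype=float) - float(baseline)
    if d.size == 0:
        raise ValueError("need at least one delta sample")
    if np.all(d == 0):
        return 0.0, 1.0
    res = stats.wilcoxon(d, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def delta_p_test(sessions: pd.DataFrame, parameter: str, seed: int = 0) -> list:
    """Run the ΔP procedure for one parameter, species by species.

    For each species: split sessions by harness, equalise group sizes with
    a seeded subsample, enumerate the between-group absolute differences,
    compute the within-group baseline, and apply the one-sided test.
    Species with an empty harness group, or without enough sessions to
    define a baseline, are skipped with a warning.
    """
    results = []
    for sp, grp in sessions.groupby("species", sort=True):
        bp = grp.loc[grp["harness"] == "backpack", parameter].dropna().to_numpy()
        ll = grp.loc[grp["harness"] == "leg-loop", parameter].dropna().to_numpy()
        if bp.size == 0 or ll.size == 0:
            warnings.warn(f"species {sp}: a harness group is empty; skipped", stacklevel=2)
            continue
        bp_eq, ll_eq = equalize_groups(bp, ll, seed=seed)
        try:
            baseline = baseline_within(bp_eq, ll_eq)
        except ValueError:
            warnings.warn(f"species {sp}: too few sessions for a baseline; skipped", stacklevel=2)
            continue
        deltas = delta_between(bp_eq, ll_eq)
        v, p = harness_comparison_test(deltas, baseline)
        results.append(
            DeltaPResult(
                species=sp, parameter=parameter, delta_samples=deltas,
                baseline=baseline, v_stat=v, p_value=p,
                n_bp=bp_eq.size, n_ll=ll_eq.size, seed=seed,
            )
        )
    return results


def validation_compare(values_a, values_b, parameter: str = "") -> dict:
    """Two-sided comparison of a parameter measured by two co-mounted tags.

    When the two lists are paired (equal length, same flights) a Wilcoxon
    signed-rank test of the paired differences against zero is used; with
    unequal lengths the function falls back to a two-sided rank-sum
    (Mann-Whitney) test, and says so in the result. Fewer than three
    observations flag the p-value as unreliable.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    reliable = min(a.size, b.size) >= 3
    if not reliable:
        warnings.warn(f"{parameter}: fewer than 3 observations; p-value unreliable", stacklevel=2)
    if a.size == b.size:
        d = a - b
        if np.all(d == 0):
            stat, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(d, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        test = "wilcoxon_signed_rank"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
        test = "wilcoxon_rank_sum"
    return {"parameter": parameter, "test": test, "statistic": stat,
            "p_value": p, "n_a": int(a.size), "n_b": int(b.size), "reliable": reliable}
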