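"""Two-stage phenotypic screen analysis on wound-recruitment counts.

A primary screen exposes one extract per well (several larvae each) and
counts neutrophils recruited to a wound; extracts whose mean count falls to
a small fraction of the vehicle-control mean become *candidates*.
Candidates are then re-tested on replicate plates and *confirmed* only if
the inhibition reproduces in every replicate and survives a one-way ANOVA
with a Dunnett many-to-one comparison against vehicle.  The result is a
funnel: conditions screened → candidates → confirmed hits.

The primary threshold (default: mean recruitment ≤ 30% of vehicle) is a
deliberately strict "near-complete block" rule; it is configurable and is
echoed in every report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import VEHICLE_LABEL

DEFAULT_THRESHOLD = 0.3
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_LARVAE = 3

PLATE_COLUMNS = ["well", "condition", "replicate", "count"]


@dataclass(frozen=True)
class HitCall:
    condition: str
    mean_count: float
    fraction_of_control: float
    stage: str  # candidate | confirmed | rejected | unresolved
    p_adj: float = float("nan")


def _validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    counts = plate["count"]
    if len(plate) and (
        (counts < 0).any() or (counts != counts.astype(int)).any()
    ):
        raise ValueError("counts must be non-negative integers")
    return plate


def score_plate(plate: pd.DataFrame, vehicle_label: str = VEHICLE_LABEL) -> pd.DataFrame:
    """Per-condition summary of one plate.

    Returns one row per condition with ``mean, sd, n, fraction_of_control``
    where ``fraction_of_control`` is the condition mean divided by the
    vehicle mean.  Raises if vehicle wells are absent or their mean count is
    zero (an assay failure: no recruitment in controls).
    """
    plate = _validate_plate(plate)
    vehicle_counts = plate.loc[plate["condition"] == vehicle_label, "count"]
    if vehicle_counts.empty:
        raise ValueError(f"no {vehicle_label!r} wells on plate")
    vehicle_mean = float(vehicle_counts.mean())
    if vehicle_mean == 0:
        raise ValueError("vehicle mean count is zero; assay failure")
    grouped = plate.groupby("condition", sort=False)["count"]
    scores = pd.DataFrame(
        {
            "condition": grouped.mean().index,
            "mean": grouped.mean().to_numpy(dtype=float),
            "sd": grouped.std(ddof=1).to_numpy(dtype=float),
            "n": grouped.size().to_numpy(dtype=int),
        }
    )
    scores["fraction_of_control"] = scores["mean"] / vehicle_mean
    return scores.reset_index(drop=True)


def call_candidates(
    scores: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    min_larvae: int = DEFAULT_MIN_LARVAE,
    vehicle_label: str = VEHICLE_LABEL,
) -> list[HitCall]:
    """Primary-screen candidate calling.

    A non-vehicle condition becomes a candidate when its
    ``fraction_of_control`` is ≤ ``threshold`` and at least ``min_larvae``
    larvae were scored.  Output is ordered by (fraction, condition label),
    deterministically.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    hits = []
    for row in scores.itertuples(index=False):
        if row.condition == vehicle_label:
            continue
        if row.n < min_larvae:
            continue
        if row.fraction_of_control <= threshold:
            hits.append(
                HitCall(
                    condition=str(row.condition),
                    mean_count=float(row.mean),
                    fraction_of_control=float(row.fraction_of_control),
                    stage="candidate",
                )
            )
    return sorted(hits, key=lambda h: (h.fraction_of_control, h.condition))


def confirm_hits(
    candidates: Sequence[HitCall],
    replicate_plates: Sequence[pd.DataFrame],
    alpha: float = DEFAULT_ALPHA,
    threshold: float = DEFAULT_THRESHOLD,
    vehicle_label: str = VEHICLE_LABEL,
) -> list[HitCall]:
    """Confirmation stage over replicate plates.

    A candidate is confirmed iff (i) its fraction-of-control is ≤
    ``threshold`` on *every* replicate plate where it appears, (ii) it
    appears on at least two replicates, and (iii) the Dunnett-adjusted
    p-value of its comparison against pooled vehicle counts, after a
    significant one-way ANOVA across all groups, is ≤ ``alpha``.  Candidates
    missing from ≥ half the replicates (fewer than two appearances) stay
    ``unresolved``.  ``alpha`` ≤ 0 confirms nothing.
    """
    if not candidates:
        return []
    plates = [_validate_plate(p) for p in replicate_plates]
    if not plates:
        return [
            HitCall(c.condition, c.mean_count, c.fraction_of_control, "unresolved")
            for c in candidates
        ]
    per_plate_scores = [score_plate(p, vehicle_label) for p in plates]
    vehicle_counts = np.concatenate(
        [
            p.loc[p["condition"] == vehicle_label, "count"].to_numpy(dtype=float)
            for p in plates
        ]
    )

    pooled_counts: dict[str, np.ndarray] = {}
    fractions: dict[str, list[float]] = {}
    for cand in candidates:
        counts = [
            p.loc[p["condition"] == cand.condition, "count"].to_numpy(dtype=float)
            for p in plates
        ]
        counts = [c for c in counts if c.size]
        if counts:
            pooled_counts[cand.condition] = np.concatenate(counts)
        fractions[cand.condition] = [
            float(
                s.loc[s["condition"] == cand.condition, "fraction_of_control"].iloc[0]
            )
            for s in per_plate_scores
            if (s["condition"] == cand.condition).any()
        ]

    testable = [
        c.condition
        for c in candidates
        if len(fractions.get(c.condition, [])) >= 2
        and pooled_counts.get(c.condition, np.array([])).size >= 2
    ]
    anova_p = float("nan")
    dunnett_p: dict[str, float] = {}
    if testable and vehicle_counts.size >= 2:
        groups = [pooled_counts[c] for c in testable]
        anova_p = float(stats.f_oneway(vehicle_counts, *groups).pvalue)
        # fixed rng: Dunnett's p-values come from randomised quadrature of
        # the multivariate t and must be reproducible across runs
        res = stats.dunnett(*groups, control=vehicle_counts, rng=0)
        dunnett_p = dict(zip(testable, (float(p) for p in res.pvalue)))

    results = []
    for cand in candidates:
        fr = fractions.get(cand.condition, [])
        pooled = pooled_counts.get(cand.condition, np.array([]))
        if len(fr) < 2:
            results.append(
                HitCall(
                    cand.condition, cand.mean_count, cand.fraction_of_control,
                    "unresolved",
                )
            )
            continue
        mean_count = float(pooled.mean())
        frac = float(mean_count / vehicle_counts.mean())
        p_adj = dunnett_p.get(cand.condition, float("nan"))
        consistent = all(f <= threshold for f in fr)
        significant = (
            alpha > 0
            and np.isfinite(anova_p)
            and anova_p <= alpha
            and np.isfinite(p_adj)
            and p_adj <= alpha
        )
        stage = "confirmed" if (consistent and significant) else "rejected"
        results.append(HitCall(cand.condition, mean_count, frac, stage, p_adj))
    return results


def screen_report(
    hit_calls: Sequence[HitCall],
    scores: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    vehicle_label: str = VEHICLE_LABEL,
) -> dict:
    """Machine-readable funnel report.

    Counts conditions screened (non-vehicle conditions in ``scores``),
    candidates and confirmed hits, and lists each call.  The inclusion chain
    confirmed ⊆ candidates ⊆ screened holds by construction.
    """
    screened = sorted(
        set(scores["condition"]) - {vehicle_label}
    )
    candidates = sorted(
        {h.condition for h in hit_calls if h.stage in ("candidate", "confirmed", "rejected", "unresolved")}
    )
    confirmed = sorted({h.condition for h in hit_calls if h.stage == "confirmed"})
    return {
        "n_screened": len(screened),
        "n_candidates": len(candidates),
        "n_confirmed": len(confirmed),
        "candidates": candidates,
        "confirmed": confirmed,
        "parameters": {
            "threshold": threshold,
            "alpha": alpha,
            "vehicle_label": vehicle_label,
        },
        "hit_calls": [asdict(h) for h in hit_calls],
    }


def report_to_text(report: dict) -> str:
    lines = [
        "screen funnel",
        f"  conditions screened : {report['n_screened']}",
        f"  primary candidates  : {report['n_candidates']}",
        f"  confirmed hits      : {report['n_confirmed']}",
        f"  threshold (fraction of control) : {report['parameters']['threshold']}",
        f"  alpha               : {report['parameters']['alpha']}",
    ]
    for h in report["hit_calls"]:
        lines.append(
            f"  {h['condition']}: stage={h['stage']} "
            f"fraction={h['fraction_of_control']:.3f} p_adj={h['p_adj']:.3g}"
        )
    return "\n".join(lines)


def run_screen(
    primary: pd.DataFrame,
    confirmation_plates: Sequence[pd.DataFrame] = (),
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    min_larvae: int = DEFAULT_MIN_LARVAE,
    vehicle_label: str = VEHICLE_LABEL,
) -> dict:
    """Score the primary plate, call candidates, confirm on replicates and
    return the funnel report."""
    scores = score_plate(primary, vehicle_label)
    candidates = call_candidates(scores, threshold, min_larvae, vehicle_label)
    if confirmation_plates:
        calls = confirm_hits(
            candidates, confirmation_plates, alpha, threshold, vehicle_label
        )
    else:
        calls = list(candidates)
    return screen_report(calls, scores, threshold, alpha, vehicle_label)


def run_simulated_screen(
    seed: int,
    n_extracts: int = 1040,
    n_inhibitors: int = 2,
    inhibitor_effect: float = 0.0,
    control_mean: float = 10.0,
    n_replicates: int = 3,
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    min_larvae: int = DEFAULT_MIN_LARVAE,
) -> tuple[dict, dict[str, float]]:
    """Simulate and analyse one complete two-stage screen.

    Generates a primary plate of ``n_extracts`` extracts with
    ``n_inhibitors`` planted inhibitors, calls candidates, simulates
    ``n_replicates`` confirmation plates for them and returns
    ``(funnel report, ground-truth effect map)``.
    """
    from .simulate import simulate_confirmation_plates, simulate_screen

    rng = np.random.default_rng(seed)
    primary_seed, confirm_seed = (int(s) for s in rng.integers(0, 2**31 - 1, 2))
    primary, truth = simulate_screen(
        n_extracts=n_extracts,
        n_inhibitors=n_inhibitors,
        inhibitor_effect=inhibitor_effect,
        control_mean=control_mean,
        seed=primary_seed,
    )
    scores = score_plate(primary)
    candidates = call_candidates(scores, threshold, min_larvae)
    plates = simulate_confirmation_plates(
        [c.condition for c in candidates],
        truth,
        n_replicates=n_replicates,
        control_mean=control_mean,
        seed=confirm_seed,
    )
    report = run_screen(primary, plates, threshold, alpha, min_larvae)
    return report, truth


def write_report(report: dict, json_path, csv_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2)
    if csv_path is not None:
        pd.DataFrame(report["hit_calls"]).to_csv(csv_path, index=False)
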