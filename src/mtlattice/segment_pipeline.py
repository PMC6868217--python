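"""Desk-scale simulation of per-MT restraints in pseudo-helical processing.

Boxed MT segments (one per ~82 A dimer repeat) each receive noisy
observations during classification/alignment: a protofilament-number
class call, an in-plane rotation angle phi, and a seam/register
hypothesis call.  Because all segments of one MT share a single
architecture, per-MT restraints -- modal protofilament class, per-MT
median phi, modal seam hypothesis -- reduce the per-segment error.
This module simulates that observation model as categorical/Gaussian
noise channels and evaluates how much each restraint recovers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SegmentRecord",
    "SegmentSimParams",
    "MTDatasetTruth",
    "simulate_segment_dataset",
    "modal_pf_assign",
    "median_phi_restraint",
    "seam_vote",
    "evaluate_recovery",
    "circular_median",
]

PF_CLASSES = (11, 12, 13, 14, 15, 16)


@dataclass(frozen=True)
class SegmentRecord:
    mt_id: int
    seg_index: int  # ordered toward the plus end
    z: float  # axial position, Angstrom
    phi_obs: float  # observed rotation angle, degrees
    class_obs: int  # protofilament-number call (11..16)
    hyp_obs: int  # seam-hypothesis call, index 2*k + register


@dataclass(frozen=True)
class SegmentSimParams:
    n_mts: int = 100
    segments_per_mt: int = 11
    box_separation: float = 82.0  # A, ~ one dimer repeat
    true_pf_choices: tuple[int, ...] = (13, 14)
    dphi_per_dimer: float = 0.0  # true skew slope, deg/dimer
    phi_noise_sd: float = 1.0  # deg
    outlier_fraction: float = 0.0  # replaced by uniform phi
    class_error_rate: float = 0.0
    hyp_error_rate: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class MTDatasetTruth:
    params: SegmentSimParams
    pf_number: tuple[int, ...]  # per MT
    phi0: tuple[float, ...]  # per MT base angle, deg
    phi_series: tuple[tuple[float, ...], ...]  # per MT true phi per segment
    hypothesis: tuple[int, ...]  # per MT true hypothesis index


def simulate_segment_dataset(
    params: SegmentSimParams,
) -> tuple[list[SegmentRecord], MTDatasetTruth]:
    """Draw a segment dataset from the categorical/Gaussian noise model.

    Per segment: phi = true phi + N(0, sd), except an outlier fraction
    redrawn uniformly on [0, 360); the class and hypothesis calls are
    correct with probability 1 - error rate, otherwise uniform over the
    alternatives.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(params.seed)
    segments: list[SegmentRecord] = []
    pf_numbers, phi0s, series, hyps = [], [], [], []
    for mt in range(params.n_mts):
        pf = int(rng.choice(params.true_pf_choices))
        n_hyp = 2 * pf
        phi0 = float(rng.uniform(0.0, 360.0))
        hyp_true = int(rng.integers(n_hyp))
        pf_numbers.append(pf)
        phi0s.append(phi0)
        hyps.append(hyp_true)
        true_phi = []
        for s in range(params.segments_per_mt):
            z = s * params.box_separation
            phi = phi0 + params.dphi_per_dimer * (z / params.box_separation)
            true_phi.append(phi)
            if rng.uniform() < params.outlier_fraction:
                phi_obs = float(rng.uniform(0.0, 360.0))
            else:
                phi_obs = float(phi + rng.normal(0.0, params.phi_noise_sd))
            if rng.uniform() < params.class_error_rate:
                alts = [c for c in PF_CLASSES if c != pf]
                class_obs = int(alts[rng.integers(len(alts))])
            else:
                class_obs = pf
            if rng.uniform() < params.hyp_error_rate:
                alts_h = [h for h in range(n_hyp) if h != hyp_true]
                hyp_obs = int(alts_h[rng.integers(len(alts_h))])
            else:
                hyp_obs = hyp_true
            segments.append(
                SegmentRecord(mt, s, z, phi_obs % 360.0, class_obs, hyp_obs)
            )
        series.append(tuple(true_phi))
    truth = MTDatasetTruth(
        params=params,
        pf_number=tuple(pf_numbers),
        phi0=tuple(phi0s),
        phi_series=tuple(series),
        hypothesis=tuple(hyps),
    )
    return segments, truth


def _mode_earliest(values: list[int]) -> int:
    """Mode; ties broken toward the value occurring earliest."""
    counts: dict[int, int] = {}
    first: dict[int, int] = {}
    for i, v in enumerate(values):
        counts[v] = counts.get(v, 0) + 1
        first.setdefault(v, i)
    best = max(counts.values())
    tied = [v for v, c in counts.items() if c == best]
    return min(tied, key=lambda v: first[v])


def modal_pf_assign(segments: list[SegmentRecord]) -> int:
    """Per-MT protofilament number: modal class of the MT's segments."""
    if not segments:
        raise ValueError("cannot assign a class to an empty MT")
    ordered = sorted(segments, key=lambda s: s.seg_index)
    return _mode_earliest([s.class_obs for s in ordered])


def circular_median(phi: np.ndarray, period: float = 360.0) -> float:
    """Median of angles via minimal-arc unwrap around the vector mean."""
    phi = np.asarray(phi, dtype=float)
    ang = phi * (2.0 * np.pi / period)
    mean = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) * period / (2.0 * np.pi)
    rel = phi - mean
    rel -= period * np.floor(rel / period + 0.5)  # into (-p/2, p/2]
    return float((mean + np.median(rel)) % period)


def median_phi_restraint(
    segments: list[SegmentRecord],
    expected_slope: float = 0.0,
    box_separation: float = 82.0,
    period: float = 360.0,
) -> list[SegmentRecord]:
    """Replace every segment's phi by the per-MT (circular) median.

    phi is first de-trended by the expected skew slope (deg per dimer,
    0 by default), the circular median taken, and the trend restored,
    so a skewed MT is restrained onto its own median line.
    """
    if not segments:
        return []
    ordered = sorted(segments, key=lambda s: s.seg_index)
    trend = np.array([expected_slope * s.z / box_separation for s in ordered])
    phi = np.array([s.phi_obs for s in ordered]) - trend
    med = circular_median(phi, period)
    return [
        SegmentRecord(s.mt_id, s.seg_index, s.z, (med + t) % 360.0, s.class_obs, s.hyp_obs)
        for s, t in zip(ordered, trend)
    ]


def seam_vote(segments: list[SegmentRecord]) -> int:
    """Per-MT seam/register hypothesis: modal call of the MT's segments."""
    if not segments:
        raise ValueError("cannot vote on an empty MT")
    ordered = sorted(segments, key=lambda s: s.seg_index)
    return _mode_earliest([s.hyp_obs for s in ordered])


def _by_mt(segments: list[SegmentRecord]) -> dict[int, list[SegmentRecord]]:
    out: dict[int, list[SegmentRecord]] = {}
    for s in segments:
        out.setdefault(s.mt_id, []).append(s)
    return out


def _circ_err(a: float, b: float, period: float = 360.0) -> float:
    d = a - b
    d -= period * np.floor(d / period + 0.5)
    return abs(d)


def evaluate_recovery(segments: list[SegmentRecord], truth: MTDatasetTruth) -> dict:
    """Accuracy of each restraint stage against the simulation truth.

    Reports per-segment and per-MT (restrained) accuracies for the
    class and hypothesis calls, mean absolute phi error before and
    after the median restraint, and -- for wrong hypothesis votes --
    whether only the register was flipped (seam position correct).
    """
    groups = _by_mt(segments)
    p = truth.params
    seg_class_ok = seg_hyp_ok = n_seg = 0
    mt_class_ok = mt_hyp_ok = register_only = 0
    raw_err, restrained_err = [], []
    for mt, segs in groups.items():
        pf = truth.pf_number[mt]
        hyp_true = truth.hypothesis[mt]
        true_phi = truth.phi_series[mt]
        ordered = sorted(segs, key=lambda s: s.seg_index)
        for s in ordered:
            n_seg += 1
            seg_class_ok += s.class_obs == pf
            seg_hyp_ok += s.hyp_obs == hyp_true
            raw_err.append(_circ_err(s.phi_obs, true_phi[s.seg_index]))
        mt_class_ok += modal_pf_assign(ordered) == pf
        vote = seam_vote(ordered)
        if vote == hyp_true:
            mt_hyp_ok += 1
        elif vote // 2 == hyp_true // 2:
            register_only += 1
        restrained = median_phi_restraint(
            ordered, expected_slope=p.dphi_per_dimer, box_separation=p.box_separation
        )
        for s in restrained:
            restrained_err.append(_circ_err(s.phi_obs, true_phi[s.seg_index]))
    n_mt = len(groups)
    return {
        "n_mts": n_mt,
        "n_segments": n_seg,
        "segment_class_accuracy": seg_class_ok / n_seg,
        "mt_class_accuracy": mt_class_ok / n_mt,
        "segment_hyp_accuracy": seg_hyp_ok / n_seg,
        "mt_hyp_accuracy": mt_hyp_ok / n_mt,
        "register_only_confusions": register_only / n_mt,
        "phi_mae_raw": float(np.mean(raw_err)),
        "phi_mae_restrained": float(np.mean(restrained_err)),
    }
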