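"""NMR observables for CKK rigidity analysis.

Chemical-shift perturbation (CSP) combines amide 1H and 15N shift
changes as sqrt((0.15*dN)^2 + dH^2) ppm.  Millisecond-exchange
flatness of a CPMG relaxation-dispersion series is summarised as the
SD/mean ratio of peak intensities across refocusing frequencies (a
flat profile -- low ratio -- indicates a rigid backbone).  CEST
profiles are scanned for minor dips betraying sparsely populated
exchanging states.  Solution-state assignments are transferred to
solid-state spectra by spectral proximity in the three independent
dimensions (HN, N, CA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ShiftRecord",
    "CSPRecord",
    "CPMGSeries",
    "CESTProfile",
    "CPMG_FREQUENCIES_HZ",
    "CPMG_RELAXATION_TIME_S",
    "csp",
    "csp_table",
    "cpmg_flatness",
    "simulate_cpmg_two_state",
    "cest_dip_scan",
    "transfer_assignments",
    "assignment_completeness",
]

# Experimental grid: CPMG fields 50..1500 Hz at a constant 40 ms
# transverse relaxation period.
CPMG_FREQUENCIES_HZ = (
    50.0, 150.0, 250.0, 350.0, 450.0, 550.0, 650.0, 750.0,
    850.0, 950.0, 1050.0, 1150.0, 1250.0, 1400.0, 1500.0,
)
CPMG_RELAXATION_TIME_S = 0.040

# Default matching tolerances (ppm): the measured 1H / 15N linewidths,
# plus a CA tolerance (not measured; configurable).
DEFAULT_TOLERANCES = {"HN": 0.1, "N": 0.6, "CA": 0.5}


@dataclass(frozen=True)
class ShiftRecord:
    residue_id: int
    residue_name: str
    HN: float  # ppm
    N: float  # ppm
    CA: float | None = None  # ppm


@dataclass(frozen=True)
class CSPRecord:
    residue_id: int
    dH: float
    dN: float
    csp: float


@dataclass(frozen=True)
class CPMGSeries:
    residue_id: int
    frequencies: tuple[float, ...]  # Hz
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.frequencies) != len(self.intensities):
            raise ValueError("frequencies and intensities must align")
        if any(f <= 0 for f in self.frequencies):
            raise ValueError("CPMG frequencies must be positive")


@dataclass(frozen=True)
class CESTProfile:
    residue_id: int
    offsets: tuple[float, ...]  # Hz, monotone
    intensities: tuple[float, ...]  # normalised

    def __post_init__(self) -> None:
        d = np.diff(self.offsets)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("CEST offsets must be monotone")


def csp(dH, dN):
    """Combined 1H/15N chemical-shift perturbation, ppm.

    csp = sqrt((0.15*dN)^2 + dH^2); accepts scalars or arrays.
    """
    dH = np.asarray(dH, dtype=float)
    dN = np.asarray(dN, dtype=float)
    if not (np.all(np.isfinite(dH)) and np.all(np.isfinite(dN))):
        raise ValueError("shift differences must be finite")
    out = np.sqrt((0.15 * dN) ** 2 + dH**2)
    return float(out) if out.ndim == 0 else out


def csp_table(free: pd.DataFrame, bound: pd.DataFrame) -> pd.DataFrame:
    """Per-residue CSPs from two shift tables (columns residue_id, HN, N)."""
    merged = free.merge(bound, on="residue_id", suffixes=("_free", "_bound"))
    dH = merged["HN_bound"] - merged["HN_free"]
    dN = merged["N_bound"] - merged["N_free"]
    return pd.DataFrame(
        {"residue_id": merged["residue_id"], "dH": dH, "dN": dN, "csp": csp(dH, dN)}
    )


def cpmg_flatness(series: CPMGSeries) -> float:
    """SD/mean ratio of CPMG intensities; ~0 means no ms exchange."""
    x = np.asarray(series.intensities, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 CPMG points")
    mean = x.mean()
    if mean == 0:
        raise ValueError("mean intensity is zero; ratio undefined")
    return float(x.std(ddof=1) / mean)


def simulate_cpmg_two_state(
    residue_id: int,
    k_ex: float,
    p_minor: float,
    delta_omega: float,
    r2_0: float = 10.0,
    i0: float = 100.0,
    frequencies=CPMG_FREQUENCIES_HZ,
    relax_time: float = CPMG_RELAXATION_TIME_S,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> CPMGSeries:
    """Forward-simulated dispersion for fast two-state exchange.

    Uses the Luz-Meiboom fast-exchange expression
    R2eff(nu) = R2_0 + (pA*pB*dw^2/kex) * (1 - (4*nu/kex)*tanh(kex/(4*nu)))
    with dw in rad/s, and intensities I = I0 * exp(-R2eff * T).
    """
    pa, pb = 1.0 - p_minor, p_minor
    nu = np.asarray(frequencies, dtype=float)
    phi = pa * pb * delta_omega**2
    r2eff = r2_0 + (phi / k_ex) * (1.0 - (4.0 * nu / k_ex) * np.tanh(k_ex / (4.0 * nu)))
    intens = i0 * np.exp(-r2eff * relax_time)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        intens = intens + rng.normal(0.0, noise_sd, size=intens.shape)
    return CPMGSeries(residue_id, tuple(nu), tuple(float(v) for v in intens))


def cest_dip_scan(profile: CESTProfile, noise_sd: float) -> list[float]:
    """Offsets of minor CEST dips (possible sparse exchanging states).

    The baseline is the median profile intensity; contiguous runs more
    than 3*noise_sd below it are dips, each reported at the offset of
    its minimum.  The deepest (main-resonance) dip is excluded, so an
    exchange-free profile yields an empty list.
    """
    offsets = np.asarray(profile.offsets, dtype=float)
    intens = np.asarray(profile.intensities, dtype=float)
    if len(offsets) < 5:
        raise ValueError("need at least 5 CEST points")
    baseline = float(np.median(intens))
    below = intens < baseline - 3.0 * noise_sd
    dips = []  # (min_intensity, offset_at_min)
    i = 0
    while i < len(below):
        if below[i]:
            j = i
            while j + 1 < len(below) and below[j + 1]:
                j += 1
            k = i + int(np.argmin(intens[i : j + 1]))
            dips.append((float(intens[k]), float(offsets[k])))
            i = j + 1
        else:
            i += 1
    if not dips:
        return []
    main = min(range(len(dips)), key=lambda n: dips[n][0])
    return [off for n, (_, off) in enumerate(dips) if n != main]


def _scaled_distance(a: ShiftRecord, b: ShiftRecord, tol: dict) -> float | None:
    """Tolerance-scaled distance in (HN, N, CA); None if out of tolerance."""
    deltas = [(a.HN - b.HN) / tol["HN"], (a.N - b.N) / tol["N"]]
    if a.CA is not None and b.CA is not None:
        deltas.append((a.CA - b.CA) / tol["CA"])
    if any(abs(d) > 1.0 for d in deltas):
        return None
    return float(np.sqrt(np.sum(np.square(deltas))))


def transfer_assignments(
    solution: list[ShiftRecord],
    observed: list[ShiftRecord],
    tolerances: dict | None = None,
) -> dict:
    """Transfer assignments by spectral proximity in (HN, N, CA).

    Greedy mutual-nearest matching: repeatedly link the globally
    closest solution/observed pair whose per-dimension differences all
    lie within tolerance (defaults: the 0.1 / 0.6 ppm 1H / 15N
    linewidths; 0.5 ppm for CA), then remove both.  Returns matches
    (solution id -> observed id with distance) and the unmatched
    records of each table.
    """
    if not solution or not observed:
        raise ValueError("both peak tables must be non-empty")
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    dist: dict[tuple[int, int], float] = {}
    for i, s in enumerate(solution):
        for j, o in enumerate(observed):
            d = _scaled_distance(s, o, tol)
            if d is not None:
                dist[(i, j)] = d
    matches = []
    used_s: set[int] = set()
    used_o: set[int] = set()
    for (i, j), d in sorted(dist.items(), key=lambda kv: kv[1]):
        if i in used_s or j in used_o:
            continue
        used_s.add(i)
        used_o.add(j)
        matches.append(
            {
                "solution_id": solution[i].residue_id,
                "observed_id": observed[j].residue_id,
                "distance": d,
            }
        )
    return {
        "matches": matches,
        "unmatched_solution": [s.residue_id for i, s in enumerate(solution) if i not in used_s],
        "unmatched_observed": [o.residue_id for j, o in enumerate(observed) if j not in used_o],
    }


def assignment_completeness(assigned_ids, construct_range: tuple[int, int]) -> float:
    """Percent of construct residues assigned, to one decimal.

    ``construct_range`` is inclusive: (1474, 1613) spans 140 residues.
    """
    lo, hi = construct_range
    if hi < lo:
        raise ValueError("empty construct range")
    residues = set(range(lo, hi + 1))
    frac = len(residues & set(int(i) for i in assigned_ids)) / len(residues)
    return round(100.0 * frac, 1)
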