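"""Independent brute-force re-implementations used as test oracles.

Pure-Python, loop-based, and deliberately naive: they re-simulate the
documented rules without sharing code with the package internals.
"""

from __future__ import annotations

import math


def descent_oracle(mzs, intensities, resolution):
    """Brute-force intensity descent on (mz, intensity) lists.

    Returns peaks as (centroid, intensity, n_points, mz_min, mz_max),
    sorted by centroid.  Mirrors the documented rules: seed on the
    maximum remaining intensity (median-m/z tied point, lower median),
    closed +/- 3 sigma window, intensity-weighted centroid.
    """
    pts = sorted(zip(mzs, intensities))
    alive = list(range(len(pts)))
    peaks = []
    while alive:
        vmax = max(pts[i][1] for i in alive)
        ties = [i for i in alive if pts[i][1] == vmax]
        seed = ties[(len(ties) - 1) // 2]
        delta = 3.0 * (pts[seed][0] / resolution) / 2.35482
        members = [i for i in alive if abs(pts[i][0] - pts[seed][0]) <= delta]
        total = sum(pts[i][1] for i in members)
        centroid = sum(pts[i][0] * pts[i][1] for i in members) / total
        mz_min, mz_max = pts[members[0]][0], pts[members[-1]][0]
        centroid = min(max(centroid, mz_min), mz_max)
        peaks.append((centroid, total, len(members), mz_min, mz_max))
        alive = [i for i in alive if i not in members]
    peaks.sort()
    return peaks


def _cosine(a, b):
    na = math.sqrt(sum(x * x for x in a))
    nb = math.sqrt(sum(x * x for x in b))
    if na == 0 or nb == 0:
        return 0.0
    return sum(x * y for x, y in zip(a, b)) / (na * nb)


def deconvolution_oracle(peaks, config, model, charge_min, charge_max, threshold):
    """Exhaustive enumeration over all (seed, charge) pairs with the same
    gathering and scoring rules as the deconvolution engine.

    ``peaks`` is a list of (mz, intensity).  Returns candidates as
    (charge, mono_mz, member_indices, score) ranked by
    (score desc, mono_mz asc, charge asc), uncapped.
    """
    from cuboidms.isotope_model import scoring_envelope
    from cuboidms.raw_model import ISOTOPE_SPACING

    peaks = sorted(peaks)
    res = config.instrument_resolution

    def delta(mz):
        return 3.0 * (mz / res) / 2.35482

    def best_in(target, tol):
        best = None
        for j, (m, i) in enumerate(peaks):
            if abs(m - target) <= tol:
                if best is None or i > peaks[best][1]:
                    best = j
        return best

    out = []
    for seed in range(len(peaks)):
        for z in range(charge_min, charge_max + 1):
            spacing = ISOTOPE_SPACING / z
            left_target = peaks[seed][0] - spacing
            left = best_in(left_target, delta(left_target))
            if left is not None and peaks[left][1] >= config.left_peak_min_ratio * peaks[seed][1]:
                continue
            members = [seed]
            for i in range(1, config.max_isotopes):
                target = peaks[seed][0] + i * spacing
                j = best_in(target, delta(target))
                if j is None:
                    break
                members.append(j)
            if len(members) < config.min_isotopes:
                continue
            mass = z * (peaks[seed][0] - config.proton_mass)
            if mass <= 0:
                continue
            obs = [peaks[j][1] for j in members]
            theo = scoring_envelope(mass, len(obs), model)
            score = _cosine(obs, theo) * (0.5 ** max(0, 3 - len(obs)))
            if score < threshold:
                continue
            out.append((z, peaks[seed][0], tuple(members), score))
    out.sort(key=lambda c: (-c[3], c[1], c[0]))
    return out


def mass_defect_filter_oracle(masses, windows):
    """Linear scan over every window for every mass."""
    kept = []
    for m in masses:
        idx = None
        for i, w in enumerate(windows):
            if w.lower_mass <= m <= w.upper_mass:
                idx = i
                break
        kept.append(idx)
    return kept
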