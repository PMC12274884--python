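"""Dendritic memory capacity and the statistical comparisons.

Capacity follows the combinatorial subunit model: a dendrite with m
independent subunits, k excitatory inputs each (s = m·k synaptic contacts)
drawing from d distinct input lines stores

    linear:     C_L = 2·log2 C(s+d-1, s)
    non-linear: C_N = 2·log2 C( C(k+d-1, k) + m - 1, m )

bits. Binomials are evaluated as exact integers before taking the log, so
the formulas hold for arbitrarily large inputs without overflow. The
non-linear model reduces to the linear one at m = 1, and at fixed s = m·k
capacity grows with the number of subunits m.
"""
from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import stats

from .topology import extract_morphology_barcode, barcode_entropy, population_image, image_distance, common_bounds


def memory_capacity_linear(s: int, d: int) -> float:
    """Capacity in bits of the linear (point-neuron) model."""
    if s < 1 or d < 1:
        raise ValueError("s and d must be positive integers")
    return 2.0 * _log2_comb(s + d - 1, s)


def memory_capacity_nonlinear(m: int, k: int, d: int) -> float:
    """Capacity in bits of the non-linear (independent-subunit) model."""
    if m < 1 or k < 1 or d < 1:
        raise ValueError("m, k and d must be positive integers")
    inner = math.comb(k + d - 1, k)
    return 2.0 * _log2_comb(inner + m - 1, m)


def _log2_comb(n: int, k: int) -> float:
    c = math.comb(n, k)
    # float(c) overflows beyond ~1e308; go through int.bit_length instead
    if c.bit_length() <= 1000:
        return math.log2(c)
    shift = c.bit_length() - 500
    return math.log2(c >> shift) + shift


def capacity_complexity_correlation(
    population,
    synapse_linear_density: float,
    d: int = 10,
    filtration: str = "path",
) -> float:
    """Spearman rank correlation between topological complexity and
    non-linear memory capacity across a population of neurons.

    Complexity is the bar-length entropy of the dendritic barcode. Capacity
    uses m = number of dendritic terminal branches (computational subunits)
    and k = round(total dendritic length · synapse density / m), floored at
    one synapse per subunit. Returns NaN (with a warning) for degenerate,
    constant series."""
    population = list(population)
    if len(population) < 3:
        raise ValueError("need at least 3 neurons")
    entropies, capacities = [], []
    for m in population:
        pb = extract_morphology_barcode(m, filtration=filtration)
        entropies.append(barcode_entropy(pb))
        n_sub = int(sum(t.n_leaves for t in m.trees(("basal", "apical"))))
        total = m.total_dendritic_length
        k = max(1, int(round(total * synapse_linear_density / n_sub)))
        capacities.append(memory_capacity_nonlinear(n_sub, k, d))
    entropies = np.asarray(entropies)
    capacities = np.asarray(capacities)
    if np.allclose(entropies, entropies[0]) or np.allclose(capacities, capacities[0]):
        warnings.warn("degenerate (constant) series; correlation undefined")
        return float("nan")
    rho, _ = stats.spearmanr(entropies, capacities)
    return float(rho)


def ks_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value).

    Underflowing p-values are floored at the smallest positive normal float
    so a p-value of exactly zero is never reported."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need at least 2 observations")
    res = stats.ks_2samp(a, b, method="asymp")
    p = max(float(res.pvalue), float(np.finfo(np.float64).tiny))
    return float(res.statistic), p


def group_variability(
    barcodes,
    group_labels,
    resolution: int = 40,
) -> tuple[float, float, float]:
    """Within- vs between-group variability of persistence barcodes.

    Distances are L1 differences of per-cell persistence images on a common
    grid. Returns (mean within-group distance, mean between-group distance,
    within/between ratio). Groups with fewer than 2 members are excluded
    from the within-group mean with a warning."""
    barcodes = list(barcodes)
    labels = np.asarray(group_labels)
    if len(barcodes) != len(labels):
        raise ValueError("labels length mismatch")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    singles = uniq[counts < 2]
    if len(singles):
        warnings.warn(f"excluding singleton group(s) {singles.tolist()} from within-group mean")
    bounds = common_bounds(barcodes)
    images = [
        population_image([pb], resolution=resolution, bounds=bounds) for pb in barcodes
    ]
    within, between = [], []
    n = len(barcodes)
    for i in range(n):
        for j in range(i + 1, n):
            dist = image_distance(images[i], images[j])
            if labels[i] == labels[j]:
                if labels[i] not in singles:
                    within.append(dist)
            else:
                between.append(dist)
    w = float(np.mean(within))
    b = float(np.mean(between))
    return w, b, w / b
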