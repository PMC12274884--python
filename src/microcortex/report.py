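"""Species-comparison report: morphometrics with KS tests, anatomy-derived
distances and densities, and topological summaries in one table."""
from __future__ import annotations

import numpy as np
import pandas as pd

from .anatomy import SpeciesParams, nn_distance_formula, dendrite_length_density
from .capacity import ks_compare
from .morphology import population_morphometrics
from .topology import extract_morphology_barcode, barcode_entropy


_MORPHO_FEATURES = [
    "total_length_apical",
    "total_length_basal",
    "branch_count_apical",
    "branch_count_basal",
    "max_radial_extent",
]


def species_comparison_report(
    pop_a,
    pop_b,
    label_a: str = "a",
    label_b: str = "b",
    params_a: SpeciesParams | None = None,
    params_b: SpeciesParams | None = None,
    filtration: str = "path",
) -> pd.DataFrame:
    """Feature-by-feature comparison of two neuron populations.

    One row per feature with the two population means, standard deviations
    and the two-sample KS p-value. When species parameter records are given,
    closed-form nearest-neighbor distances and neuropil densities are
    appended (single printed values; no test applies)."""
    ma = population_morphometrics(pop_a)
    mb = population_morphometrics(pop_b)
    rows = []
    for feat in _MORPHO_FEATURES:
        a, b = ma[feat].to_numpy(float), mb[feat].to_numpy(float)
        stat, p = ks_compare(a, b)
        rows.append(
            {
                "feature": feat,
                f"mean_{label_a}": a.mean(),
                f"sd_{label_a}": a.std(),
                f"mean_{label_b}": b.mean(),
                f"sd_{label_b}": b.std(),
                "ks_statistic": stat,
                "ks_p": p,
            }
        )
    ea = [barcode_entropy(extract_morphology_barcode(m, filtration=filtration)) for m in pop_a]
    eb = [barcode_entropy(extract_morphology_barcode(m, filtration=filtration)) for m in pop_b]
    stat, p = ks_compare(ea, eb)
    rows.append(
        {
            "feature": "barcode_entropy",
            f"mean_{label_a}": float(np.mean(ea)),
            f"sd_{label_a}": float(np.std(ea)),
            f"mean_{label_b}": float(np.mean(eb)),
            f"sd_{label_b}": float(np.std(eb)),
            "ks_statistic": stat,
            "ks_p": p,
        }
    )
    for params, label in ((params_a, label_a), (params_b, label_b)):
        if params is None:
            continue
        rows.append(
            {
                "feature": f"nn_distance_all_{label}",
                f"mean_{label}": nn_distance_formula(params.neuron_density),
            }
        )
        rows.append(
            {
                "feature": f"dendrite_length_density_{label}",
                f"mean_{label}": dendrite_length_density(
                    params.synapse_volume_density, params.synapse_linear_density
                ),
            }
        )
    return pd.DataFrame(rows)
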