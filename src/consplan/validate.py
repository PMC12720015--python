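"""Truth-recovery validation on virtual-species landscapes.

Because virtual species carry their exact true ranges, the whole modelling
chain can be scored against truth: the ensemble's binary range is compared
with the known range cell-by-cell and summarized by the true skill
statistic (sensitivity + specificity − 1 over all grid cells).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synth
from .grids import BinaryRange, GridSpec
from .sdm import ALGORITHMS, EnsembleSDM, confusion_metrics

__all__ = ["truth_tss", "recovery_experiment"]


def truth_tss(predicted: BinaryRange, truth: BinaryRange) -> float:
    """TSS of a predicted range against the known true range, over all cells."""
    if predicted.grid != truth.grid:
        raise ValueError("grid mismatch")
    _, _, tss = confusion_metrics(truth.mask.ravel(), predicted.mask.ravel())
    return tss


def recovery_experiment(
    seed: int,
    n_species: int = 20,
    nrows: int = 60,
    ncols: int = 60,
    n_occurrences: int = 200,
    n_layers: int = 10,
    autocorr_range_km: float = 8.0,
    prevalence_range: tuple[float, float] = (0.05, 0.25),
    algorithms=ALGORITHMS,
) -> pd.DataFrame:
    """Fit the ensemble to noise-free virtual species and score against truth.

    Each species is a random logistic function of 2-5 layers; occurrences
    are drawn uniformly from the true range (no observation noise).  Returns
    a per-species table with the realized prevalence, the ensemble's
    occupied-cell counts, and the truth-recovery TSS.
    """
    grid = GridSpec(nrows, ncols)
    rng = np.random.default_rng(seed)
    stack = synth.generate_env_stack(
        grid, n_layers, autocorr_range_km, seed=int(rng.integers(2**31))
    )
    names = stack.layer_names
    rows = []
    for i in range(n_species):
        for _ in range(20):
            k = int(rng.integers(2, min(5, len(names)) + 1))
            chosen = rng.choice(names, size=k, replace=False)
            coef = {"intercept": float(rng.normal(0, 0.5))}
            coef.update({n: float(rng.normal(0, 2.0)) for n in chosen})
            prevalence = float(rng.uniform(*prevalence_range))
            try:
                vs = synth.define_virtual_species(
                    stack, coef, prevalence, species_id=f"vs{i + 1:03d}"
                )
                break
            except ValueError:
                continue
        else:
            raise RuntimeError("could not draw a non-degenerate species")
        occs = synth.sample_occurrences(
            vs, n_occurrences, seed=int(rng.integers(2**31))
        )
        model = EnsembleSDM.from_occurrences(
            occs, stack, species_id=vs.species_id, algorithms=algorithms
        )
        results = model.fit(seed=int(rng.integers(2**31)))
        if results.is_unmodelled:
            rows.append(
                {"species": vs.species_id, "c_true": vs.true_range_current.c,
                 "c_predicted": np.nan, "tss_vs_truth": np.nan,
                 "unmodelled": True}
            )
            continue
        predicted = results.binarize()
        rows.append(
            {
                "species": vs.species_id,
                "c_true": vs.true_range_current.c,
                "c_predicted": predicted.c,
                "tss_vs_truth": truth_tss(predicted, vs.true_range_current),
                "unmodelled": False,
            }
        )
    return pd.DataFrame(rows)
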