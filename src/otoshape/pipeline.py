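"""End-to-end convenience pipeline: simulate (or load), describe, fit growth,
discriminate, and partition growth-rate variance.

`run_study` reproduces the full analysis chain on one dataset:

1. simulate the population and its otolith outlines;
2. compute normalized Fourier (or wavelet) descriptors, mirroring left
   otoliths first;
3. detrend descriptors against fish length within locations;
4. fit the von Bertalanffy growth curve and derive the per-fish growth
   index G;
5. stepwise-DFA classification of the three genotypes (leave-one-out), the
   two-group AA-vs-BB analysis, and the assignment of AB fish along the
   AA-BB discriminant axis;
6. the three-way Type III ANOVA of G on genotype, location and cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .descriptors import DescriptorMatrix, describe_outlines, detrend
from .discriminate import (AbAssignment, ClassificationResult, fit_lda,
                           assign_heterozygotes, loo_classify, stepwise_select)
from .groupstats import AnovaTable, anova_type3
from .growth import GrowthIndex, VBGFFit, fit_vbgf, growth_index
from .synthetic import SimConfig, generate_study


@dataclass
class StudyResult:
    fish: pd.DataFrame
    descriptors: DescriptorMatrix
    vbgf: VBGFFit
    G: GrowthIndex
    three_group: ClassificationResult
    two_group: ClassificationResult
    ab_assignment: AbAssignment | None
    anova: AnovaTable


def add_growth_index(fish: pd.DataFrame,
                     anchor_ages=(6.0, 10.0, 14.0)) -> tuple[pd.DataFrame, VBGFFit]:
    """Fit the growth curve on the full sample and append a G column."""
    fit = fit_vbgf(fish["age"], fish["length"], anchor_ages=anchor_ages)
    gi = growth_index(fit, fish)
    out = fish.copy()
    out["G"] = gi.G
    return out, fit


def classification_features(matrix: DescriptorMatrix, fish: pd.DataFrame,
                            add: tuple[str, ...] = ()) -> pd.DataFrame:
    """Descriptor columns plus optional centered-cohort / G columns."""
    X = matrix.data.copy()
    for extra in add:
        if extra == "cohort":
            X["cohort"] = fish["cohort"] - fish["cohort"].mean()
        elif extra == "G":
            X["G"] = fish["G"]
        else:
            raise ValueError(f"unknown extra feature {extra!r}")
    return X


def run_study(config: SimConfig, kind: str = "fourier",
              add: tuple[str, ...] = ("cohort", "G"),
              selection_mode: str = "fixed") -> StudyResult:
    fish, outlines = generate_study(config)
    matrix = describe_outlines(outlines, kind=kind)
    matrix, _ = detrend(matrix, fish["length"], fish["location"])
    fish, fit = add_growth_index(fish)
    gi = growth_index(fit, fish)

    X3 = classification_features(matrix, fish, add=add)
    three = loo_classify(X3, fish["genotype"], selection_mode=selection_mode)

    homo = fish["genotype"].isin(["AA", "BB"])
    X2 = X3.loc[homo.to_numpy()]
    two = loo_classify(X2, fish.loc[homo.to_numpy(), "genotype"],
                       selection_mode=selection_mode)
    sel2 = stepwise_select(X2, fish.loc[homo.to_numpy(), "genotype"])
    feats = sel2.selected or list(X2.columns)
    model2 = fit_lda(X2[feats], fish.loc[homo.to_numpy(), "genotype"],
                     selection=sel2)
    has_ab = (fish["genotype"] == "AB").to_numpy()
    ab = assign_heterozygotes(model2, X3.loc[has_ab]) if has_ab.any() else None

    anova = anova_type3(fish, response="G",
                        factors=["genotype", "location", "cohort"])
    return StudyResult(fish=fish, descriptors=matrix, vbgf=fit, G=gi,
                       three_group=three, two_group=two, ab_assignment=ab,
                       anova=anova)
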