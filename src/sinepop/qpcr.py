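"""Absolute qPCR quantification of SINE genomic copy number.

A dilution series of a plasmid standard gives a regression of cycle threshold
(Ct) on log10 template copies; unknowns are quantified off that curve and
normalized to copies per haploid genome via the input DNA mass and the
species genome size (3.534 pg for C. nasus).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sinepop.tables import GENOME_SIZE_PG

#: Amplification-efficiency sanity band for the slope (cycles per log10).
SLOPE_BAND = (-3.6, -3.1)


class EfficiencyWarning(UserWarning):
    """Standard-curve slope outside the usual amplification-efficiency band."""


@dataclass(frozen=True)
class StandardCurve:
    slope: float
    intercept: float
    r2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("a valid standard curve has negative slope")


@dataclass
class CopyNumberEstimate:
    sample_id: str
    mean_ct: float
    copies_in_reaction: float
    input_mass_pg: float
    genomes_in_reaction: float
    copies_per_genome: float
    replicate_cv: float


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of Ct on log10(copies).

    Requires >= 3 points spanning >= 2 log10 units.  Emits
    :class:`EfficiencyWarning` when the slope falls outside ``SLOPE_BAND``.
    """
    if len(points) < 3:
        raise ValueError("standard curve needs at least 3 points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all standards have the same log10 copy number")
    if np.ptp(x) < 2.0:
        raise ValueError("standards must span at least 2 log10 units")
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue**2)
    if not (SLOPE_BAND[0] <= slope <= SLOPE_BAND[1]):
        warnings.warn(
            f"slope {slope:.3f} outside efficiency band {SLOPE_BAND}", EfficiencyWarning
        )
    return StandardCurve(slope=slope, intercept=intercept, r2=r2, n_points=len(points))


def quantify(ct: float, curve: StandardCurve) -> float:
    """Copies in the reaction implied by a Ct on the standard curve."""
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def per_genome(
    copies_in_reaction: float,
    input_mass_pg: float,
    genome_size_pg: float = GENOME_SIZE_PG,
) -> float:
    """Copies per haploid genome given the DNA mass loaded in the reaction."""
    if input_mass_pg <= 0 or copies_in_reaction <= 0 or genome_size_pg <= 0:
        raise ValueError("copies, input mass and genome size must be positive")
    return copies_in_reaction * genome_size_pg / input_mass_pg


def quantify_plate(plate: pd.DataFrame, genome_size_pg: float = GENOME_SIZE_PG):
    """Fit the standards of a plate and quantify every unknown.

    The plate has columns sample_id, role in {standard, unknown},
    log10_copies (standards only), ct, input_mass_pg.  Replicates of an
    unknown are averaged on the Ct scale before quantification.
    Returns (curve, list of CopyNumberEstimate).
    """
    std = plate[plate["role"] == "standard"]
    curve = fit_standard_curve(list(zip(std["log10_copies"], std["ct"])))
    estimates = []
    unknowns = plate[plate["role"] == "unknown"]
    for sample_id, sub in unknowns.groupby("sample_id", sort=True):
        cts = sub["ct"].to_numpy(dtype=float)
        mean_ct = float(cts.mean())
        cv = float(cts.std(ddof=1) / mean_ct) if len(cts) > 1 else 0.0
        mass = float(sub["input_mass_pg"].iloc[0])
        copies = quantify(mean_ct, curve)
        genomes = mass / genome_size_pg
        estimates.append(
            CopyNumberEstimate(
                sample_id=str(sample_id),
                mean_ct=mean_ct,
                copies_in_reaction=copies,
                input_mass_pg=mass,
                genomes_in_reaction=genomes,
                copies_per_genome=copies / genomes,
                replicate_cv=cv,
            )
        )
    return curve, estimates


def compare_groups(
    estimates: list[CopyNumberEstimate], grouping: dict[str, str]
) -> dict:
    """Group means and one-way ANOVA between ecotypes and within each ecotype.

    ``grouping`` maps a sample's population to its ecotype; a sample id of
    the form "POP_xx" is assigned by its population prefix.  Requires >= 2
    estimates per group.
    """
    def pop_of(sample_id: str) -> str:
        return sample_id.split("_")[0]

    by_pop: dict[str, list[float]] = {}
    for est in estimates:
        by_pop.setdefault(pop_of(est.sample_id), []).append(est.copies_per_genome)
    by_eco: dict[str, list[float]] = {}
    for pop, vals in by_pop.items():
        if pop not in grouping:
            raise ValueError(f"population {pop!r} absent from grouping")
        by_eco.setdefault(grouping[pop], []).extend(vals)
    for name, vals in list(by_pop.items()) + list(by_eco.items()):
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 estimates")
    f_between, p_between = stats.f_oneway(*by_eco.values())
    within: dict[str, tuple[float, float]] = {}
    for eco in sorted(by_eco):
        pops = [by_pop[p] for p in sorted(by_pop) if grouping[p] == eco]
        if len(pops) >= 2:
            f, p = stats.f_oneway(*pops)
            within[eco] = (float(f), float(p))
    return {
        "population_means": {p: float(np.mean(v)) for p, v in sorted(by_pop.items())},
        "ecotype_means": {e: float(np.mean(v)) for e, v in sorted(by_eco.items())},
        "anova_between_ecotypes": (float(f_between), float(p_between)),
        "anova_within_ecotype": within,
    }
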