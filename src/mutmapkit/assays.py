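"""Closed-form quantitative assays used alongside the mapping analysis.

* anthocyanin content from three-wavelength absorbance of an acidified
  methanol extract,
* relative transcript abundance by the 2^-ddCt method,
* Pearson chi-square test of a Mendelian segregation ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = [
    "AnthocyaninMeasurement",
    "QpcrSample",
    "SegregationCounts",
    "anthocyanin_concentration",
    "relative_expression_ddct",
    "segregation_test",
]


@dataclass(frozen=True)
class AnthocyaninMeasurement:
    """Absorbances at 530/620/650 nm, extract volume (ml), tissue mass (g)."""

    od530: float
    od620: float
    od650: float
    volume_ml: float = 1.0
    mass_g: float = 0.1

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError("mass_g must be > 0")
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be > 0")


def anthocyanin_concentration(meas: AnthocyaninMeasurement) -> float:
    """[(OD530 - OD620) - 0.1*(OD650 - OD620)] * v / m.

    OD620 corrects for turbidity, the OD650 term for chlorophyll overlap;
    the result is in absorbance units * ml / g fresh weight (no molar
    conversion, as no extinction coefficient is assumed).
    """
    net = (meas.od530 - meas.od620) - 0.1 * (meas.od650 - meas.od620)
    return net * meas.volume_ml / meas.mass_g


@dataclass(frozen=True)
class QpcrSample:
    """Ct values (cycles) for target and reference gene in test vs control."""

    ct_target_test: float
    ct_reference_test: float
    ct_target_control: float
    ct_reference_control: float


def relative_expression_ddct(s: QpcrSample) -> float:
    """Fold change 2^-ddCt with a single reference gene.

    dCt = Ct(target) - Ct(reference) within each condition; ddCt is the test
    minus control difference, so equal amplification efficiencies cancel.
    """
    dct_test = s.ct_target_test - s.ct_reference_test
    dct_control = s.ct_target_control - s.ct_reference_control
    return 2.0 ** -(dct_test - dct_control)


@dataclass(frozen=True)
class SegregationCounts:
    n_dominant_phenotype: int
    n_recessive_phenotype: int
    expected_ratio: tuple[float, float] = (3.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_dominant_phenotype < 0 or self.n_recessive_phenotype < 0:
            raise ValueError("counts must be >= 0")
        if self.n_dominant_phenotype + self.n_recessive_phenotype < 1:
            raise ValueError("at least one individual required")
        if min(self.expected_ratio) <= 0:
            raise ValueError("expected ratio parts must be > 0")


def segregation_test(
    counts: SegregationCounts, continuity_correction: bool = False
) -> tuple[float, float, int]:
    """Pearson chi-square of observed phenotype counts against the expected
    ratio (default 3:1, the F2 expectation for a single recessive allele).

    Returns (chi_square, p_value, df=1). No continuity correction by
    default; Yates' correction available by flag.
    """
    n = counts.n_dominant_phenotype + counts.n_recessive_phenotype
    a, b = counts.expected_ratio
    expected = (n * a / (a + b), n * b / (a + b))
    observed = (counts.n_dominant_phenotype, counts.n_recessive_phenotype)
    if continuity_correction:
        chi2 = sum((abs(o - e) - 0.5) ** 2 / e for o, e in zip(observed, expected))
    else:
        chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, 1
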