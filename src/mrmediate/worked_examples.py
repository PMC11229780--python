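"""Published worked-example effect sizes for the proportion-mediated rule.

Total and indirect effect estimates (linear-probability scale) from a
gut-microbiome → blood-metabolite/cytokine → rheumatoid-arthritis
mediation analysis.  Each row carries the total causal effect of the
microbial trait on RA, the two-step (product-of-coefficients) indirect
effect, and the MVMR (difference-in-coefficients) indirect effect, plus
the published proportion-mediated percentages — ``None`` where the
published table reports NA because the indirect effect opposes the total
effect in sign.  Inputs are printed to 3 significant figures, so
recomputed proportions can differ from the published ones by up to about
0.15 percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MediationWorkedExample:
    exposure: str
    mediator: str
    total_effect: float
    two_step_effect: float
    two_step_prop_pct: float | None
    mvmr_effect: float
    mvmr_prop_pct: float | None


MEDIATION_WORKED_EXAMPLES: tuple[MediationWorkedExample, ...] = (
    MediationWorkedExample("OTU99_5 (Sutterella) abundance", "Alanine",
                           -6.89e-04, -1.45e-04, 21.10, 7.73e-05, None),
    MediationWorkedExample("TestASV_4 (Alistipes) prevalence",
                           "3-methyl-2-oxovalerate",
                           6.76e-04, 1.67e-04, 24.73, -4.87e-06, None),
    MediationWorkedExample("OTU99_78 (Clostridiales) prevalence",
                           "3-methyl-2-oxovalerate",
                           -4.92e-04, -2.86e-04, 58.22, -2.40e-04, 48.70),
    MediationWorkedExample("OTU97_69 (Clostridiales) prevalence",
                           "3-methyl-2-oxovalerate",
                           -4.93e-04, -2.86e-04, 58.07, -2.61e-04, 52.89),
    MediationWorkedExample("TestASV_32 (Ruminococcaceae) prevalence",
                           "ADSGEGDFXAEGGGVR*",
                           -2.45e-04, 9.66e-06, None, -5.50e-05, 22.44),
    MediationWorkedExample("TestASV_32 (Ruminococcaceae) prevalence",
                           "X-11793--oxidized bilirubin*",
                           -2.45e-04, 1.81e-05, None, -8.68e-05, 35.40),
    MediationWorkedExample("TestASV_6 (Subdoligranulum) abundance", "TSG-6",
                           -7.30e-04, -5.65e-05, 7.75, 1.23e-04, None),
    MediationWorkedExample("G_Bacteroidetes prevalence", "TSG-6",
                           4.60e-04, -4.50e-05, None, 2.37e-05, 5.16),
)
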