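"""Independent, definition-based oracles used only by the tests.

These re-implement the derived quantities directly from their defining
formulas, sharing no code with the package, so agreement is a genuine
cross-check rather than a tautology.
"""

import numpy as np


def naive_jip_panel(f0, f300, fj, fi, fm, sm=0.0, variant="as_printed"):
    """Straight transcription of each JIP-test formula, one line per symbol."""
    vj = (fj - f0) / (fm - f0)
    vi = (fi - f0) / (fm - f0)
    m0 = 4.0 * (f300 - f0) / (fm - f0)
    phi_po = 1.0 - (f0 / fm)
    psi_eo = 1.0 - vj
    phi_eo = (1.0 - (f0 / fm)) * (1.0 - vj)
    phi_ro = (1.0 - (f0 / fm)) * (1.0 - vi)
    out = {
        "VJ": vj,
        "VI": vi,
        "M0": m0,
        "Sm": sm,
        "N": sm * m0 * (1.0 / vj),
        "phi_Po": phi_po,
        "psi_Eo": psi_eo,
        "phi_Eo": phi_eo,
        "phi_Ro": phi_ro,
        "ABS_RC": m0 * (1.0 / vj) * (1.0 / phi_po),
        "TR0_RC": m0 * (1.0 / vj),
        "ET0_RC": m0 * (1.0 / vj) * psi_eo,
        "DI0_RC": m0 * (1.0 / vj) * (1.0 / phi_po) - m0 * (1.0 / vj),
        "ABS_CS": fm,
        "TR0_CS": phi_po * fm,
        "DI0_CS": fm - phi_po * fm,
        "RC_CS": phi_po * (vj / m0) * fm,
        "PI_ABS": (phi_po * (vj / m0))
        * (phi_po / (1.0 - phi_po))
        * (psi_eo / (1.0 - psi_eo)),
    }
    if variant == "as_printed":
        out["RE0_RC"] = m0 * (1.0 / vj) * psi_eo * phi_ro
        out["ET0_CS"] = phi_po * phi_eo * fm
        out["RE0_CS"] = phi_eo * phi_ro * fm
    else:
        out["RE0_RC"] = m0 * (1.0 / vj) * (1.0 - vi)
        out["ET0_CS"] = phi_eo * fm
        out["RE0_CS"] = phi_ro * fm
    return out


def anova_f_by_definition(groups):
    """One-way ANOVA F from between/within mean squares, by definition."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    k = len(groups)
    n = all_values.size
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    return ms_between / ms_within
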