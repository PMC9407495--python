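"""Published coefficient blocks used as desk-check inputs.

These are the printed statistics of the source study's path-analysis table,
color-regression table and fitted color structural models. They are inputs
for arithmetic reproduction checks (the raw climate/color data behind them
were never deposited); nothing here is a computed output of this package.
"""

from __future__ import annotations

#: Single-predictor path-analysis blocks: response -> (factor, r = P, D).
#: With one predictor the direct path coefficient equals the correlation.
PATH_SINGLE: dict[str, tuple[str, float, float]] = {
    "Y_HY": ("X_RH", -0.720, 0.518),
    "Y_CGC": ("X_AMAT", -0.476, 0.227),
    "Y_CSA": ("X_AMAT", -0.559, 0.312),
    "L": ("X_AMAT", -0.729, 0.531),
}

#: The apigenin two-predictor block: per factor (r, direct P, indirect via
#: the co-predictor, decision coefficient D).
PATH_Y_AP: dict[str, dict[str, float]] = {
    "X_AMAT": {"r": -0.470, "direct": -0.723, "indirect": 0.253, "D": 0.157},
    "X_ASD": {"r": -0.173, "direct": -0.523, "indirect": 0.350, "D": -0.093},
}

#: Predictor intercorrelation of the apigenin block, recovered from the
#: printed indirect/direct ratio (0.350 / -0.723 = 0.253 / -0.523 = -0.484)
#: and verified by back-substitution into the r = P + indirect identity.
PATH_Y_AP_INTERCORR: float = -0.484

#: Standardized edge sets of the three fitted peel-color models
#: (climate factor and anthocyanin/flavonol mediator -> color axis).
SEM_EDGES: dict[str, dict[tuple[str, str], float]] = {
    "L": {
        ("X_MAW", "Y_PG"): 0.45,
        ("Y_PG", "L"): 0.75,
        ("X_MAW", "L"): 0.21,
    },
    "a": {
        ("X_AMAT", "Y_CGC"): -0.50,
        ("X_MAW", "Y_CGC"): 0.41,
        ("Y_CGC", "a"): 0.88,
        ("X_AMAT", "a"): -0.46,
        ("X_MAW", "a"): 0.36,
    },
    "b": {
        ("X_AMT", "Y_QI"): -0.44,
        ("X_AMAT", "Y_QI"): -0.53,
        ("X_MW", "Y_QI"): -0.30,
        ("Y_QI", "b"): -0.77,
        ("X_AAP", "b"): 0.16,
        ("X_AMT", "b"): 0.10,
        ("X_AMAT", "b"): 0.06,
    },
}

#: Printed indirect coefficients that are arithmetically consistent with
#: their stated edge products: (model, source, mediator) -> value at 2 d.p.
SEM_INDIRECTS_CONSISTENT: dict[tuple[str, str, str], float] = {
    ("a", "X_AMAT", "Y_CGC"): -0.44,
    ("a", "X_MAW", "Y_CGC"): 0.36,
    ("L", "X_MAW", "Y_PG"): 0.34,
}

#: Content-on-color regression rows: response -> (coef_a, coef_b,
#: intercept, R, R2, F); n = 26 provenances, k = 2 color predictors.
REGRESSION_ROWS: dict[str, tuple[float, float, float, float, float, float]] = {
    "Y_QI": (-0.854, 0.383, 77.186, 0.891, 0.795, 44.511),
    "Y_AP": (0.050, -0.042, 1.589, 0.818, 0.668, 23.180),
    "Y_PH": (0.088, -0.067, 2.719, 0.849, 0.722, 57.247),
    "Y_PG": (0.093, -0.059, 1.376, 0.808, 0.653, 56.694),
    "Y_CGC": (0.111, -0.084, 5.379, 0.913, 0.833, 29.806),
    "Y_CSA": (0.099, -0.092, 7.606, 0.912, 0.831, 21.646),
    "Y_CGT": (0.098, -0.091, 5.709, 0.819, 0.671, 23.420),
}

#: Row pairs whose printed F statistics are mutually exchanged relative to
#: their printed R2 (each printed F falls inside the 3-d.p. rounding-slack
#: interval implied by the *other* row's R2, and far outside its own): a
#: typesetting artifact of the source table.
F_ROW_SWAPS: tuple[tuple[str, str], ...] = (("Y_PH", "Y_CGC"), ("Y_PG", "Y_CSA"))

#: Reported variance percentages of the flavonoid-profile PCA.
PCA_PC1_PCT: float = 48.36
PCA_CUMULATIVE_PCT: float = 62.95
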