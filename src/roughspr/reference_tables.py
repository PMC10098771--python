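"""Published reference values for the regression test suite.

Performance parameters of the ideal uniform gold sensor, the five rough
operating points a–e, and the enhancement-ratio decomposition, as printed
in the original study's summary tables.  Each entry carries a ``location``
provenance string.  These are *expected values for tests*, never inputs to
the simulation itself.
"""

from __future__ import annotations

_UNIFORM = {
    "S": 122.59,
    "n0_sin_theta_sp": 1.440,
    "FWHM": 0.41,
    "delta_I": 0.90,
    "I_sp": 0.007,
    "FoM1": 299.00,
    "FoM2": 980.66,
}

# operating points: (h, cl) and the per-model performance values
_POINTS = {
    "point_a": {
        "h": 3, "cl": 10,
        "no_sidewall": {"S": -379.88, "n0_sin_theta_sp": 1.481,
                        "FWHM": 0.58, "delta_I": 0.88, "I_sp": 0.018,
                        "FoM1": -654.97, "FoM2": -1677.42},
        "sidewall": {"S": -379.88, "n0_sin_theta_sp": 1.481,
                     "FWHM": 0.58, "delta_I": 0.88, "I_sp": 0.018,
                     "FoM1": -654.97, "FoM2": -1677.42},
    },
    "point_b": {
        "h": 10, "cl": 30,
        "no_sidewall": {"S": 85.31, "n0_sin_theta_sp": 1.506,
                        "FWHM": 0.79, "delta_I": 0.47, "I_sp": 0.41,
                        "FoM1": 107.98, "FoM2": 92.52},
        "sidewall": {"S": 85.31, "n0_sin_theta_sp": 1.506,
                     "FWHM": 0.79, "delta_I": 0.47, "I_sp": 0.41,
                     "FoM1": 107.98, "FoM2": 92.52},
    },
    "point_c": {
        "h": 12, "cl": 20,
        "no_sidewall": {"S": 996.11, "n0_sin_theta_sp": 1.495,
                        "FWHM": 0.66, "delta_I": 0.13, "I_sp": 0.72,
                        "FoM1": 1509.26, "FoM2": 590.75},
        "sidewall": {"S": 1280.00, "n0_sin_theta_sp": 1.496,
                     "FWHM": 0.65, "delta_I": 0.15, "I_sp": 0.70,
                     "FoM1": 1969.23, "FoM2": 833.81},
    },
    "point_d": {
        "h": 9, "cl": 8,
        "no_sidewall": {"S": 1191.13, "n0_sin_theta_sp": 1.486,
                        "FWHM": 0.67, "delta_I": 0.10, "I_sp": 0.69,
                        "FoM1": 1777.80, "FoM2": 616.84},
        "sidewall": {"S": 1608.02, "n0_sin_theta_sp": 1.490,
                     "FWHM": 0.67, "delta_I": 0.14, "I_sp": 0.60,
                     "FoM1": 2400.02, "FoM2": 1020.33},
    },
    "point_e": {
        "h": 16, "cl": 15,
        "no_sidewall": {"S": None, "n0_sin_theta_sp": 1.466,
                        "FWHM": 0.77, "delta_I": 0.001, "I_sp": 0.75,
                        "FoM1": None, "FoM2": None},
        "sidewall": {"S": None, "n0_sin_theta_sp": 1.473,
                     "FWHM": 0.75, "delta_I": 0.003, "I_sp": 0.69,
                     "FoM1": None, "FoM2": None},
    },
}

# enhancement-ratio decomposition (total roughness, LSPR part, protein part)
_ER = {
    "point_a": {"S": (-3.10, -3.10, 0.0),
                "FoM1": (-2.19, -2.19, 0.0),
                "FoM2": (-1.71, -1.71, 0.0)},
    "point_b": {"S": (0.70, 0.70, 0.0),
                "FoM1": (0.36, 0.36, 0.0),
                "FoM2": (0.09, 0.09, 0.0)},
    "point_c": {"S": (10.44, 8.13, 2.31),
                "FoM1": (6.59, 5.05, 1.54),
                "FoM2": (0.85, 0.60, 0.25)},
    "point_d": {"S": (13.12, 9.72, 3.40),
                "FoM1": (8.03, 5.95, 2.08),
                "FoM2": (1.04, 0.63, 0.41)},
}

_RESPONSIVITY = {
    "uniform_r_squared": 0.9985,
    "no_sidewall_r_squared": 0.9990,
    "sidewall_r_squared": 0.9990,
}


def load() -> dict:
    """Flat table ``key -> {"value": ..., "location": str}``."""
    out = {}
    for metric, value in _UNIFORM.items():
        out[f"uniform.{metric}"] = {
            "value": value,
            "location": "ideal-uniform-sensor summary",
        }
    for point, data in _POINTS.items():
        out[f"{point}.h"] = {
            "value": data["h"], "location": f"{point} definition"
        }
        out[f"{point}.cl"] = {
            "value": data["cl"], "location": f"{point} definition"
        }
        for model in ("no_sidewall", "sidewall"):
            for metric, value in data[model].items():
                out[f"{point}.{model}.{metric}"] = {
                    "value": value,
                    "location": "operating-point performance table",
                }
    for point, metrics in _ER.items():
        for metric, (rough, lspr, protein) in metrics.items():
            out[f"{point}.ER_{metric}_roughness"] = {
                "value": rough, "location": "enhancement-ratio table"
            }
            out[f"{point}.ER_{metric}_LSPR"] = {
                "value": lspr, "location": "enhancement-ratio table"
            }
            out[f"{point}.ER_{metric}_protein"] = {
                "value": protein, "location": "enhancement-ratio table"
            }
    for key, value in _RESPONSIVITY.items():
        out[f"responsivity.{key}"] = {
            "value": value,
            "location": "protein-thickness linearity discussion",
        }
    return out
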