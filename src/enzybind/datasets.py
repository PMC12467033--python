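"""Published worked-example inputs for the six porphyrin-enzyme systems.

The original study reports, for each porphyrin (TAPP, THPP, TCPP and the
Fe/Ni/Cu complexes of TCPP) against α-amylase ("amy") and α-glucosidase
("glu"):

* apparent Michaelis constants Km (mmol/L) and maximal velocities Vmax
  (ΔOD/min) at six inhibitor concentrations (μg/mL), from which the
  secondary-plot constants Ki and Kis are recomputed here;
* Stern-Volmer constants Ksv (L/mol), binding-site numbers n and binding
  constants Ka (L/mol) at 298/304/310 K, from which the Van't Hoff
  thermodynamics are recomputed.

These printed tables are the package's desk-scale inputs; the raw curves
behind them are not public.
"""

from __future__ import annotations

# (enzyme, compound) -> {"inhibitor": [...μg/mL], "km": [...mmol/L],
#                        "vmax": [...ΔOD/min]}
KINETIC_TABLES: dict[tuple[str, str], dict[str, list[float]]] = {
    ("amy", "TAPP"): {
        "inhibitor": [0, 2, 4, 6, 8, 10],
        "km": [3.9047, 4.3893, 4.8719, 5.1449, 5.4460, 5.7081],
        "vmax": [0.1826, 0.1670, 0.1562, 0.1425, 0.1328, 0.1243],
    },
    ("amy", "THPP"): {
        "inhibitor": [0, 20, 30, 40, 50, 60],
        "km": [3.6644, 7.8640, 8.0378, 8.3899, 8.6487, 8.8467],
        "vmax": [0.1390, 0.0740, 0.0580, 0.0491, 0.0426, 0.0376],
    },
    ("amy", "TCPP"): {
        "inhibitor": [0, 25, 50, 100, 150, 200],
        "km": [2.5848, 4.9029, 6.3562, 8.8655, 10.3380, 11.3676],
        "vmax": [0.1244, 0.1046, 0.0872, 0.0709, 0.0583, 0.0496],
    },
    ("amy", "Fe-TCPP"): {
        "inhibitor": [0, 25, 50, 100, 150, 200],
        "km": [2.4394, 2.7329, 2.9384, 3.2079, 3.3360, 3.4920],
        "vmax": [0.1387, 0.1143, 0.0972, 0.0748, 0.0601, 0.0512],
    },
    ("amy", "Ni-TCPP"): {
        "inhibitor": [0, 40, 80, 120, 160, 200],
        "km": [3.6368, 3.6229, 3.6134, 3.6072, 3.6027, 3.5987],
        "vmax": [0.1831, 0.1456, 0.1238, 0.1032, 0.0901, 0.0799],
    },
    ("amy", "Cu-TCPP"): {
        "inhibitor": [0, 25, 50, 100, 150, 200],
        "km": [2.5129, 2.8021, 3.1685, 3.5949, 3.9016, 4.2470],
        "vmax": [0.1155, 0.1101, 0.1050, 0.0923, 0.0860, 0.0785],
    },
    ("glu", "THPP"): {
        "inhibitor": [0, 1, 2.5, 5, 7.5, 10],
        "km": [6.7070, 7.1219, 7.3949, 7.5880, 7.6790, 7.7319],
        "vmax": [0.2310, 0.1528, 0.1013, 0.0649, 0.0489, 0.0377],
    },
    ("glu", "Ni-TCPP"): {
        "inhibitor": [0, 5, 7.5, 10, 15, 25],
        "km": [2.0514, 3.0491, 3.3243, 3.5279, 3.8090, 4.1248],
        "vmax": [0.1649, 0.1036, 0.0909, 0.0791, 0.0628, 0.0444],
    },
    ("glu", "Fe-TCPP"): {
        "inhibitor": [0, 16, 32, 48, 64, 80],
        "km": [1.4377, 2.6958, 3.3979, 3.9231, 4.1566, 4.3847],
        "vmax": [0.1076, 0.0771, 0.0601, 0.0502, 0.0416, 0.0361],
    },
    ("glu", "TCPP"): {
        "inhibitor": [0, 5, 25, 50, 100, 150],
        "km": [1.8019, 2.5045, 4.4087, 5.5731, 7.1021, 7.7894],
        "vmax": [0.1499, 0.1369, 0.1016, 0.0745, 0.0516, 0.0389],
    },
    ("glu", "Cu-TCPP"): {
        "inhibitor": [0, 5, 10, 25, 50, 100],
        "km": [2.7842, 3.3657, 3.8284, 4.7824, 5.4948, 6.4626],
        "vmax": [0.1689, 0.1496, 0.1344, 0.1028, 0.0718, 0.0473],
    },
    ("glu", "TAPP"): {
        "inhibitor": [0, 12.5, 15, 17.5, 20, 22.5],
        "km": [2.0896, 3.9347, 4.2527, 4.5048, 4.7611, 5.0007],
        "vmax": [0.0969, 0.0791, 0.0767, 0.0736, 0.0711, 0.0688],
    },
}

# Published secondary-plot constants (μg/mL) for cross-checking; Kis is None
# where the study treats the system as non-competitive.
PUBLISHED_KI: dict[tuple[str, str], tuple[float, float | None]] = {
    ("amy", "TAPP"): (8.7057, 21.2847),
    ("amy", "THPP"): (9.2445, 23.1012),
    ("amy", "TCPP"): (19.9216, 132.4382),
    ("amy", "Fe-TCPP"): (69.5865, 117.2152),
    ("amy", "Ni-TCPP"): (157.9542, None),
    ("amy", "Cu-TCPP"): (135.8043, 420.9420),
    ("glu", "THPP"): (1.6508, None),
    ("glu", "Ni-TCPP"): (3.8703, 9.2257),
    ("glu", "Fe-TCPP"): (9.8917, 40.4085),
    ("glu", "TCPP"): (9.5746, 52.5334),
    ("glu", "Cu-TCPP"): (13.7332, 38.9429),
    ("glu", "TAPP"): (9.4635, 55.1227),
}

TEMPERATURES_K = (298.0, 304.0, 310.0)

# (enzyme, compound) -> {"ksv": [...L/mol], "n": [...], "ka": [...L/mol]}
# indexed in the order of TEMPERATURES_K; Ksv printed as x1e4, Ka as x1e5.
BINDING_TABLES: dict[tuple[str, str], dict[str, list[float]]] = {
    ("amy", "TAPP"): {
        "ksv": [4.07e4, 3.37e4, 3.07e4],
        "n": [1.48, 1.40, 1.31],
        "ka": [52.90e5, 21.79e5, 7.46e5],
    },
    ("amy", "THPP"): {
        "ksv": [8.90e4, 8.20e4, 7.64e4],
        "n": [1.19, 1.16, 1.12],
        "ka": [5.65e5, 3.65e5, 2.46e5],
    },
    ("amy", "TCPP"): {
        "ksv": [4.04e4, 3.55e4, 3.01e4],
        "n": [1.36, 1.28, 1.20],
        "ka": [12.54e5, 5.01e5, 2.18e5],
    },
    ("amy", "Fe-TCPP"): {
        "ksv": [4.32e4, 3.36e4, 3.29e4],
        "n": [1.65, 1.38, 1.05],
        "ka": [944.30e5, 40.38e5, 2.13e5],
    },
    ("amy", "Ni-TCPP"): {
        "ksv": [9.78e4, 8.47e4, 7.11e4],
        "n": [1.44, 1.19, 0.99],
        "ka": [99.31e5, 5.75e5, 0.61e5],
    },
    ("amy", "Cu-TCPP"): {
        "ksv": [4.37e4, 4.33e4, 4.32e4],
        "n": [0.93, 0.84, 0.78],
        "ka": [0.20e5, 0.10e5, 0.06e5],
    },
    ("glu", "THPP"): {
        "ksv": [7.40e4, 6.97e4, 6.69e4],
        "n": [1.29, 1.23, 1.16],
        "ka": [15.49e5, 8.01e5, 3.39e5],
    },
    ("glu", "Ni-TCPP"): {
        "ksv": [17.73e4, 14.23e4, 12.31e4],
        "n": [1.03, 1.04, 1.03],
        "ka": [2.34e5, 2.09e5, 1.83e5],
    },
    ("glu", "Fe-TCPP"): {
        "ksv": [14.52e4, 13.18e4, 12.20e4],
        "n": [1.01, 1.00, 0.98],
        "ka": [1.65e5, 1.26e5, 1.02e5],
    },
    ("glu", "TCPP"): {
        "ksv": [7.45e4, 4.90e4, 4.22e4],
        "n": [1.30, 1.19, 1.07],
        "ka": [13.73e5, 3.17e5, 0.97e5],
    },
    ("glu", "Cu-TCPP"): {
        "ksv": [7.35e4, 6.74e4, 5.05e4],
        "n": [1.44, 1.25, 1.03],
        "ka": [55.21e5, 7.38e5, 0.69e5],
    },
    ("glu", "TAPP"): {
        "ksv": [6.25e4, 5.71e4, 5.66e4],
        "n": [1.14, 1.09, 1.01],
        "ka": [2.78e5, 1.42e5, 0.65e5],
    },
}

# Native α-amylase amide-I composition (percent per structure class), used
# as the default ground truth of the FTIR synthetic generator.
AMY_SECONDARY_STRUCTURE = {
    "alpha_helix": 24.58,
    "beta_sheet": 27.34,
    "beta_turn": 23.64,
    "random_coil": 14.10,
    "beta_antiparallel": 10.34,
}


def kinetic_fits(enzyme: str, compound: str):
    """The published apparent-constant table as a list of KineticFit."""
    from .kinetics import KineticFit

    table = KINETIC_TABLES[(enzyme, compound)]
    return [
        KineticFit.from_constants(km, vmax, conc)
        for conc, km, vmax in zip(table["inhibitor"], table["km"], table["vmax"])
    ]


def binding_pairs(enzyme: str, compound: str) -> list[tuple[float, float]]:
    """Published (temperature, Ka) pairs for a system."""
    table = BINDING_TABLES[(enzyme, compound)]
    return list(zip(TEMPERATURES_K, table["ka"]))
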