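"""Synthetic moss-survey concentration tables with known ground truth.

The generator emulates the statistical anatomy of a two-site-class moss
biomonitoring survey of trace elements, so that every analysis stage can be
tested against a programmed truth:

* log-normal marginals with element-specific baselines on realistic mg/kg
  scales, plus occasional multiplicative outliers (right skew, mean >
  median, SD > MADN);
* a shared "crustal" latent factor coupling the soil-dust elements
  (Al, Sc, V, Fe, Co, Cr, Th, U);
* an "anthropogenic" latent factor coupling the emission-derived elements
  (Pb, Cd, Zn, As, Sb) together with Mo and Ba, on which Mn loads
  *negatively* — Mn is modelled as a physiologically regulated antagonist
  of its partner elements (Zn, Mo, Ba, Pb, Cd);
* multiplicative site-class shifts: most anthropogenic-route elements
  higher in the mountain class, Mn the reverse.

On the log scale each cell is

``ln C_ik = ln(baseline_k) + loading_k * F(i) + ln(shift_k) * mountain(i)
+ N(0, noise_sigma) [+ ln(outlier_magnitude) with prob outlier_rate]``

The ground truth treats the site-class indicator as one more shared (weak,
binary) factor: a pair is expected-``p``/``n`` when its elements share any
factor with concordant/discordant signs, and expected-``r`` only when the
elements are statistically independent.  Factor-coupled pairs are flagged
``strong`` — these are the pairs a permutation classifier at n = 30 should
recover essentially always; shift-only coupling is real but weaker.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ConcentrationTable

__all__ = ["GeneratorConfig", "GroundTruth", "generate", "write_fixture", "DEFAULT_PANEL"]

#: The 29-element survey panel.
DEFAULT_PANEL = (
    "Na", "Mg", "Al", "Cl", "K", "Ca", "Sc", "V", "Cr", "Mn", "Fe", "Co",
    "Cu", "Zn", "As", "Br", "Rb", "Sr", "Mo", "Cd", "Sb", "Cs", "Ba", "La",
    "Ce", "Hf", "Pb", "Th", "U",
)

#: Typical lowland geometric-mean concentrations, mg/kg dry weight.
DEFAULT_BASELINES = {
    "Na": 166.0, "Mg": 1489.0, "Al": 695.0, "Cl": 378.0, "K": 5887.0,
    "Ca": 2163.0, "Sc": 0.1, "V": 1.3, "Cr": 1.6, "Mn": 400.0, "Fe": 392.0,
    "Co": 0.2, "Cu": 6.4, "Zn": 40.0, "As": 0.2, "Br": 1.7, "Rb": 41.0,
    "Sr": 7.4, "Mo": 0.13, "Cd": 0.3, "Sb": 0.17, "Cs": 0.3, "Ba": 12.0,
    "La": 0.4, "Ce": 0.8, "Hf": 0.11, "Pb": 4.9, "Th": 0.1, "U": 0.04,
}

DEFAULT_CRUSTAL = ("Al", "V", "Sc", "Fe", "Co", "Cr", "Th", "U")
DEFAULT_ANTHROPOGENIC = ("Pb", "Cd", "Zn", "As", "Sb")
DEFAULT_ANTAGONIST_PARTNERS = ("Zn", "Mo", "Ba", "Pb", "Cd")
#: Elements shifted up in the mountain site class (Mn is shifted down).
DEFAULT_SHIFTED_UP = ("As", "Ba", "Ca", "Cd", "Cl", "Cr", "Cu", "Mo", "Pb", "Sr", "Zn")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic survey.

    Defaults encode a 30-sample, two-site-class survey whose latent factor
    strength (loading 0.3 against baseline log-noise 0.09) yields strong,
    reliably classifiable within-factor proportionality, and whose 1.5-fold
    site-class shifts are detectable by a rank test at 15 samples per group.
    Outliers (1% of cells, 5-fold) supply the right-skew, heavy-tail
    character of field concentration tables.
    """

    n_per_group: int = 15
    elements: tuple[str, ...] = DEFAULT_PANEL
    baselines: dict = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    crustal_set: tuple[str, ...] = DEFAULT_CRUSTAL
    anthropogenic_set: tuple[str, ...] = DEFAULT_ANTHROPOGENIC
    antagonist: str = "Mn"
    antagonist_partners: tuple[str, ...] = DEFAULT_ANTAGONIST_PARTNERS
    factor_loading: float = 0.3
    noise_sigma: float = 0.09
    group_shift: dict = field(default_factory=dict)  # overrides, mountain/lowland
    default_shift: float = 1.5
    shifted_up: tuple[str, ...] = DEFAULT_SHIFTED_UP
    outlier_rate: float = 0.01
    outlier_magnitude: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_per_group < 2:
            problems.append("n_per_group must be at least 2")
        if len(self.elements) < 2:
            problems.append("need at least 2 elements")
        if len(set(self.elements)) != len(self.elements):
            problems.append("element labels must be distinct")
        for name in ("factor_loading", "noise_sigma", "default_shift", "outlier_magnitude"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive")
        if not 0.0 <= self.outlier_rate <= 1.0:
            problems.append("outlier_rate must lie in [0, 1]")
        for s in (self.crustal_set, self.anthropogenic_set, self.antagonist_partners):
            unknown = set(s) - set(self.elements)
            if unknown:
                problems.append(f"set members not in panel: {sorted(unknown)}")
        if self.antagonist not in self.elements:
            problems.append("antagonist not in panel")
        for e, s in self.group_shift.items():
            if s <= 0:
                problems.append(f"group_shift[{e}] must be positive")
        if problems:
            raise ValueError("invalid generator config: " + "; ".join(problems))

    # --- derived structure -------------------------------------------------

    def factor_loadings(self) -> dict[str, dict[str, float]]:
        """Per-element loadings on the two latent factors."""
        loads: dict[str, dict[str, float]] = {e: {} for e in self.elements}
        for e in self.crustal_set:
            loads[e]["crustal"] = self.factor_loading
        anthro_members = set(self.anthropogenic_set) | set(self.antagonist_partners)
        for e in anthro_members:
            loads[e]["anthropogenic"] = self.factor_loading
        loads[self.antagonist]["anthropogenic"] = -self.factor_loading
        return loads

    def log_shifts(self) -> dict[str, float]:
        """Mountain-vs-lowland log shift per element."""
        shifts = {e: 0.0 for e in self.elements}
        for e in self.shifted_up:
            shifts[e] = float(np.log(self.default_shift))
        shifts[self.antagonist] = -float(np.log(self.default_shift))
        for e, s in self.group_shift.items():
            shifts[e] = float(np.log(s))
        return shifts


@dataclass
class GroundTruth:
    """Programmed dependence structure of a generated table.

    ``pair_labels`` maps each unordered pair to its expected covariability
    code; ``strong`` flags the factor-coupled pairs (shift-only coupling is
    genuine but weak); ``independent_pairs`` lists the pairs with no shared
    structure at all.  ``group_direction`` records, per element, which site
    class was programmed higher ("mountain", "lowland" or "none").
    """

    pair_labels: dict[tuple[str, str], str]
    strong: dict[tuple[str, str], bool]
    group_direction: dict[str, str]

    @property
    def independent_pairs(self) -> list[tuple[str, str]]:
        return [p for p, lab in self.pair_labels.items() if lab == "r"]

    def strong_pairs(self, code: str | None = None) -> list[tuple[str, str]]:
        out = [p for p, s in self.strong.items() if s]
        if code is not None:
            out = [p for p in out if self.pair_labels[p] == code]
        return out

    def label_matrix(self, elements) -> pd.DataFrame:
        mat = pd.DataFrame("", index=list(elements), columns=list(elements), dtype=object)
        for (a, b), lab in self.pair_labels.items():
            mat.loc[a, b] = mat.loc[b, a] = lab
        return mat

    def to_json(self) -> str:
        payload = {
            "pair_labels": [
                {"pair": list(p), "label": lab, "strong": self.strong[p]}
                for p, lab in sorted(self.pair_labels.items())
            ],
            "group_direction": self.group_direction,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        pair_labels = {}
        strong = {}
        for rec in payload["pair_labels"]:
            p = tuple(rec["pair"])
            pair_labels[p] = rec["label"]
            strong[p] = bool(rec["strong"])
        return cls(pair_labels, strong, payload["group_direction"])


def _derive_truth(config: GeneratorConfig) -> GroundTruth:
    loads = config.factor_loadings()
    shifts = config.log_shifts()
    pair_labels: dict[tuple[str, str], str] = {}
    strong: dict[tuple[str, str], bool] = {}
    for a, b in itertools.combinations(config.elements, 2):
        key = tuple(sorted((a, b)))
        factor_dot = sum(
            loads[a][f] * loads[b][f] for f in loads[a] if f in loads[b]
        )
        shift_dot = shifts[a] * shifts[b]
        if factor_dot != 0.0:
            pair_labels[key] = "p" if factor_dot > 0 else "n"
            strong[key] = True
        elif shift_dot != 0.0:
            pair_labels[key] = "p" if shift_dot > 0 else "n"
            strong[key] = False
        else:
            pair_labels[key] = "r"
            strong[key] = False
    direction = {
        e: ("mountain" if s > 0 else "lowland" if s < 0 else "none")
        for e, s in shifts.items()
    }
    return GroundTruth(pair_labels, strong, direction)


def generate(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[ConcentrationTable, GroundTruth]:
    """Draw one synthetic survey table plus its ground truth.

    ``seed`` overrides ``config.seed``; the draw is fully reproducible.
    Lowland samples come first, then mountain samples; parks are labelled
    with rotating abbreviations within each class.
    """
    config = config or GeneratorConfig()
    config.validate()
    if seed is not None:
        config = GeneratorConfig(**{**asdict_shallow(config), "seed": int(seed)})
    rng = np.random.default_rng(config.seed)
    elements = list(config.elements)
    n = 2 * config.n_per_group
    D = len(elements)
    loads = config.factor_loadings()
    shifts = config.log_shifts()
    factors = {
        "crustal": rng.normal(size=n),
        "anthropogenic": rng.normal(size=n),
    }
    mountain = np.repeat([0.0, 1.0], config.n_per_group)
    log_c = np.empty((n, D))
    for k, e in enumerate(elements):
        base = float(config.baselines.get(e, 1.0))
        col = np.log(base) + rng.normal(0.0, config.noise_sigma, size=n)
        for f, lam in loads[e].items():
            col += lam * factors[f]
        col += shifts[e] * mountain
        log_c[:, k] = col
    outliers = rng.random((n, D)) < config.outlier_rate
    log_c += np.log(config.outlier_magnitude) * outliers

    lowland_parks = ["BT", "Wi", "Ka", "Ro", "Ks"]
    mountain_parks = ["GS", "Oj", "Bg", "Sw"]
    parks = [lowland_parks[i % len(lowland_parks)] for i in range(config.n_per_group)]
    parks += [mountain_parks[i % len(mountain_parks)] for i in range(config.n_per_group)]
    sample_ids = [
        f"{parks[i]}{i + 1:02d}" for i in range(n)
    ]
    meta = pd.DataFrame(
        {
            "park": parks,
            "site_class": ["lowland"] * config.n_per_group
            + ["mountain"] * config.n_per_group,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    values = pd.DataFrame(np.exp(log_c), index=meta.index, columns=elements)
    table = ConcentrationTable(values=values, meta=meta)
    return table, _derive_truth(config)


def asdict_shallow(config: GeneratorConfig) -> dict:
    """Shallow dict of a config (tuples and dicts kept as-is)."""
    return {f: getattr(config, f) for f in config.__dataclass_fields__}


def write_fixture(table: ConcentrationTable, truth: GroundTruth, path) -> dict:
    """Write ``table.csv`` and ``truth.json`` under *path*; returns the paths.

    The table round-trips bit-identically through
    :func:`mosscoda.io.read_concentration_table` and the bytes are a pure
    function of the generating seed.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    table_path = path / "table.csv"
    truth_path = path / "truth.json"
    table.to_csv(table_path)
    truth_path.write_text(truth.to_json())
    return {"table": str(table_path), "truth": str(truth_path)}
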