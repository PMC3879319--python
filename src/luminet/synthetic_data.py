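"""Synthetic expression and cohort data with planted ground truth.

The generator emulates the two substrates of the pipeline:

* a microarray-style expression matrix (probes x samples) with a binary
  class label per sample, in which a configurable number of "informative"
  probes carry a class-conditional mean shift and a "panel" subset carries
  planted signed pairwise dependencies via a directed-acyclic linear
  structural model — so probe ranking and interaction inference can be
  scored against known truth;

* a patient cohort table with per-patient H-scores, binary biomarkers drawn
  at configured odds ratios against an exposure group, and right-censored
  exponential event times under proportional hazards — so the association
  screen and the survival machinery can be scored against known truth.

The module also packages the published contingency tables of a ~1,000
patient breast-cancer tissue-microarray cohort relating nuclear DACH1
protein expression to clinicopathological factors and other biomarkers;
these serve as exact fixtures for the chi-square screen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from luminet.dataset import ExpressionDataset
from luminet.exceptions import ConfigError, FixtureLookupError

__all__ = [
    "ExpressionConfig",
    "CohortConfig",
    "GroundTruth",
    "ExpressionDataset",
    "generate_expression",
    "generate_cohort",
    "published_contingency",
    "available_contingency_tables",
]


@dataclass(frozen=True)
class ExpressionConfig:
    """Parameters of the planted expression-matrix generator.

    Defaults are a scaled-down stand-in for a 22,283-probe / 278-sample
    microarray study (164 vs 114 class split): 500 probes, 200 samples with
    the same ~59/41 class balance. ``effect_size`` is the standardized mean
    difference between classes for informative probes; panel probes follow
    a linear DAG with coefficients of magnitude in
    ``edge_coefficient_range`` and residual noise ``noise_sd``.
    """

    n_probes: int = 500
    n_samples: int = 200
    n_class1: int = 118
    n_informative: int = 20
    effect_size: float = 1.5
    panel_size: int = 20
    n_planted_edges: int = 10
    edge_coefficient_range: tuple[float, float] = (0.5, 1.0)
    noise_sd: float = 0.3
    nonlinear: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for fname in ("n_probes", "n_samples", "n_class1"):
            if getattr(self, fname) < 1:
                raise ConfigError(f"{fname} must be positive")
        for fname in ("n_informative", "panel_size", "n_planted_edges"):
            if getattr(self, fname) < 0:
                raise ConfigError(f"{fname} must be >= 0")
        if self.n_class1 > self.n_samples:
            raise ConfigError("n_class1 must be <= n_samples")
        if self.n_informative + self.panel_size > self.n_probes:
            raise ConfigError(
                "n_informative + panel_size must be <= n_probes"
            )
        lo, hi = self.edge_coefficient_range
        if not (0 < lo <= hi):
            raise ConfigError(
                "edge_coefficient_range must be 0 < low <= high (nonzero coefficients)"
            )
        if self.panel_size > 1:
            max_edges = self.panel_size * (self.panel_size - 1) // 2
        else:
            max_edges = 0
        if self.n_planted_edges > max_edges:
            raise ConfigError(
                f"n_planted_edges={self.n_planted_edges} exceeds the "
                f"{max_edges} possible DAG edges for panel_size={self.panel_size}"
            )
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the planted patient-cohort generator.

    ``association_odds`` maps marker name -> odds ratio of marker positivity
    given exposure positivity; ``hazard_ratio`` is the exposed-group hazard
    ratio for event times (exponential baseline with median survival at half
    of ``followup_max`` months).
    """

    n_patients: int = 500
    marker_list: tuple[str, ...] = ("marker_a", "marker_b")
    association_odds: tuple[float, ...] = (2.0, 1.0)
    baseline_prevalence: tuple[float, ...] = (0.4, 0.4)
    hazard_ratio: float = 1.0
    censor_rate: float = 0.2
    followup_max: float = 240.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be positive")
        if not (
            len(self.marker_list)
            == len(self.association_odds)
            == len(self.baseline_prevalence)
        ):
            raise ConfigError(
                "marker_list, association_odds and baseline_prevalence "
                "must have equal lengths"
            )
        if any(o <= 0 for o in self.association_odds):
            raise ConfigError("association_odds must be > 0")
        if any(not 0 < p < 1 for p in self.baseline_prevalence):
            raise ConfigError("baseline_prevalence must be in (0, 1)")
        if self.hazard_ratio <= 0:
            raise ConfigError("hazard_ratio must be > 0")
        if not 0 <= self.censor_rate <= 1:
            raise ConfigError("censor_rate must be in [0, 1]")
        if self.followup_max <= 0:
            raise ConfigError("followup_max must be > 0")


@dataclass
class GroundTruth:
    """What the generator planted, for scoring downstream stages."""

    informative_probe_ids: list[str] = field(default_factory=list)
    planted_edges: list[tuple[str, str, int, float]] = field(default_factory=list)
    marker_odds: dict[str, float] = field(default_factory=dict)
    true_hazard_ratio: float | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "informative_probe_ids": self.informative_probe_ids,
                "planted_edges": [list(e) for e in self.planted_edges],
                "marker_odds": self.marker_odds,
                "true_hazard_ratio": self.true_hazard_ratio,
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "GroundTruth":
        d = json.loads(payload)
        return cls(
            informative_probe_ids=list(d["informative_probe_ids"]),
            planted_edges=[
                (str(s), str(t), int(sg), float(c))
                for s, t, sg, c in d["planted_edges"]
            ],
            marker_odds={str(k): float(v) for k, v in d["marker_odds"].items()},
            true_hazard_ratio=(
                None
                if d["true_hazard_ratio"] is None
                else float(d["true_hazard_ratio"])
            ),
        )


def generate_expression(
    config: ExpressionConfig,
) -> tuple[ExpressionDataset, GroundTruth]:
    """Generate a probes x samples matrix with planted structure.

    Informative probes get a class-conditional mean shift of
    ``effect_size`` pooled standard deviations. Panel probes follow
    ``x_target = sum(coeff * x_source) + noise`` over a random DAG with
    signed coefficients (optionally ``tanh``-squashed sources when
    ``nonlinear``); all remaining probes are independent standard normals.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(config.n_probes)))
    probe_ids = [f"P{i:0{width}d}" for i in range(1, config.n_probes + 1)]
    sample_ids = [f"S{j:04d}" for j in range(1, config.n_samples + 1)]

    labels = np.zeros(config.n_samples, dtype=int)
    labels[rng.permutation(config.n_samples)[: config.n_class1]] = 1

    values = rng.normal(0.0, 1.0, size=(config.n_probes, config.n_samples))

    special = rng.permutation(config.n_probes)[
        : config.n_informative + config.panel_size
    ]
    informative_idx = np.sort(special[: config.n_informative])
    panel_idx = np.sort(special[config.n_informative :])

    # class-predictive probes: baseline sd is 1, so the shift IS the
    # standardized effect size
    values[np.ix_(informative_idx, np.flatnonzero(labels == 1))] += config.effect_size

    # panel probes: topological order = panel order; edges go earlier -> later
    planted_edges: list[tuple[str, str, int, float]] = []
    k = config.panel_size
    if k > 1 and config.n_planted_edges > 0:
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
        chosen = rng.choice(len(pairs), size=config.n_planted_edges, replace=False)
        incoming: dict[int, list[tuple[int, float]]] = {}
        for c in sorted(chosen):
            i, j = pairs[c]
            lo, hi = config.edge_coefficient_range
            coeff = float(rng.uniform(lo, hi)) * (1 if rng.random() < 0.5 else -1)
            incoming.setdefault(j, []).append((i, coeff))
            planted_edges.append(
                (
                    probe_ids[panel_idx[i]],
                    probe_ids[panel_idx[j]],
                    int(np.sign(coeff)),
                    coeff,
                )
            )
        panel_vals = rng.normal(0.0, 1.0, size=(k, config.n_samples))
        for j in range(k):
            if j in incoming:
                acc = rng.normal(0.0, config.noise_sd, size=config.n_samples)
                for i, coeff in incoming[j]:
                    src = np.tanh(panel_vals[i]) if config.nonlinear else panel_vals[i]
                    acc = acc + coeff * src
                panel_vals[j] = acc
        values[panel_idx] = panel_vals

    dataset = ExpressionDataset(
        values=values,
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        labels=labels,
    )
    truth = GroundTruth(
        informative_probe_ids=[probe_ids[i] for i in informative_idx],
        planted_edges=planted_edges,
    )
    return dataset, truth


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a patient cohort with planted associations and hazards.

    Exposure (the candidate marker, encoded both as a 0/1 flag and an
    H-score that is 0 when absent) is Bernoulli(1/2). Each binary marker is
    drawn with ``logit P(marker) = logit(baseline) + log(OR) * exposure``.
    Event times are exponential under proportional hazards with the exposed
    group's hazard multiplied by ``hazard_ratio``; random censoring is
    uniform on (0, followup_max) applied with probability ``censor_rate``,
    plus administrative censoring at ``followup_max``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    exposure = (rng.random(n) < 0.5).astype(int)
    hscore = np.where(exposure == 1, rng.integers(5, 301, size=n), 0)

    frame = pd.DataFrame(
        {
            "patient_id": [f"PT{i:05d}" for i in range(1, n + 1)],
            "exposure": exposure,
            "hscore": hscore,
        }
    )
    marker_odds: dict[str, float] = {}
    for name, odds, prev in zip(
        config.marker_list, config.association_odds, config.baseline_prevalence
    ):
        logit = np.log(prev / (1 - prev)) + np.log(odds) * exposure
        p = 1.0 / (1.0 + np.exp(-logit))
        frame[name] = (rng.random(n) < p).astype(int)
        marker_odds[name] = float(odds)

    base_rate = np.log(2.0) / (config.followup_max / 2.0)
    rate = base_rate * config.hazard_ratio**exposure
    event_time = rng.exponential(1.0 / rate)
    random_censor = np.where(
        rng.random(n) < config.censor_rate,
        rng.uniform(1e-6, config.followup_max, size=n),
        np.inf,
    )
    horizon = np.minimum(random_censor, config.followup_max)
    frame["time"] = np.minimum(event_time, horizon)
    frame["event"] = (event_time <= horizon).astype(int)

    truth = GroundTruth(
        marker_odds=marker_odds, true_hazard_ratio=float(config.hazard_ratio)
    )
    return frame, truth


# ---------------------------------------------------------------------------
# Published reference contingency tables (DACH1 tissue-microarray cohort).
# Counts are (row = factor level or marker status) x (DACH1 absent, present).
# ---------------------------------------------------------------------------

_COLS = ("DACH1 absent", "DACH1 present")

_CONTINGENCY: dict[str, tuple[list[list[int]], list[str]]] = {
    # clinicopathological factors
    "Age group": (
        [[40, 35], [128, 176], [124, 197], [96, 197]],
        ["<40", "40-50", "51-60", "60-75"],
    ),
    "Menopause": ([[174, 214], [214, 391]], ["Premenopausal", "Postmenopausal"]),
    "Tumour Size": ([[178, 307], [207, 293]], ["<=1.5 cm", ">1.5 cm"]),
    "Tumour Stage": ([[241, 362], [112, 183], [34, 56]], ["1", "2", "3"]),
    "Tumour Grade": ([[35, 134], [94, 226], [256, 240]], ["1", "2", "3"]),
    "Nottingham Prognostic Index": (
        [[75, 200], [233, 309], [77, 92]],
        ["Good", "Moderate", "Poor"],
    ),
    "Tumour type": (
        [[260, 314], [28, 85], [50, 136], [20, 3], [4, 14], [17, 40]],
        [
            "Ductal NST",
            "Lobular",
            "Tubular & tubular mixed",
            "Medullary",
            "Special type",
            "Mixed NST/lobular/special",
        ],
    ),
    "Distant metastasis": ([[268, 425], [118, 172]], ["Absent", "Present"]),
    "Tumour recurrence": ([[231, 353], [150, 238]], ["Absent", "Present"]),
    "Vascular invasion": (
        [[222, 325], [33, 80], [129, 191]],
        ["Negative", "Probable", "Definite"],
    ),
    "Endocrine therapy": ([[261, 331], [106, 208]], ["Untreated", "Treated"]),
    # biomarkers (rows = marker absent / present)
    "ER": ([[181, 78], [185, 493]], ["Absent", "Present"]),
    "PgR": ([[212, 191], [150, 376]], ["Absent", "Present"]),
    "CK18": ([[86, 39], [260, 502]], ["Absent", "Present"]),
    "CK19": ([[50, 50], [320, 531]], ["Absent", "Present"]),
    "HER2": ([[311, 524], [62, 64]], ["Absent", "Present"]),
    "E-cadherin": ([[145, 213], [217, 362]], ["Absent", "Present"]),
    "EGFR": ([[249, 425], [76, 83]], ["Absent", "Present"]),
    "CK5/6": ([[267, 534], [104, 48]], ["Absent", "Present"]),
    "CK14": ([[304, 518], [63, 55]], ["Absent", "Present"]),
    "p53": ([[227, 457], [135, 114]], ["Absent", "Present"]),
    "MIB1": ([[59, 154], [138, 128]], ["Absent", "Present"]),
    "FOXA1": ([[178, 174], [105, 231]], ["Absent", "Present"]),
    "CD71": ([[90, 220], [188, 204]], ["Absent", "Present"]),
    "PELP1": ([[250, 369], [36, 61]], ["Absent", "Present"]),
    "RERG": ([[214, 306], [58, 121]], ["Absent", "Present"]),
}

_ALIASES = {"NPI": "Nottingham Prognostic Index"}


def available_contingency_tables() -> list[str]:
    """Names of the packaged reference contingency tables."""
    return sorted(_CONTINGENCY)


def published_contingency(table_name: str) -> pd.DataFrame:
    """Return a packaged reference contingency table by name.

    Rows are factor levels (or marker absent/present), columns are the
    DACH1 absent/present groups; values are patient counts.
    """
    key = _ALIASES.get(table_name, table_name)
    if key not in _CONTINGENCY:
        for cand in _CONTINGENCY:
            if cand.lower() == str(key).lower():
                key = cand
                break
    if key not in _CONTINGENCY:
        raise FixtureLookupError(
            f"unknown table {table_name!r}; available: "
            + ", ".join(available_contingency_tables())
        )
    counts, row_labels = _CONTINGENCY[key]
    return pd.DataFrame(counts, index=row_labels, columns=list(_COLS))
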