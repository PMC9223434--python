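"""Executable demonstration models and case-study parameter inventories.

Two kinds of fixtures live here:

* Analytically solvable toy models (``make_linear_chain``) used as oracles
  for the sensitivity indices, plus two ILLUSTRATIVE pathway surrogates:
  a p53/Mdm2-like negative-feedback oscillator and a JAK/STAT-like
  receptor-to-transcript cascade.  The surrogates reproduce the qualitative
  dynamics of the two case-study pathways (oscillatory vs. aperiodic
  response, and the direction of drug-like parameter reductions); they are
  NOT the published kinetic models of those pathways, whose equations and
  fitted rate constants are defined in the original modeling literature.
  Anyone holding those models can wrap them in :class:`OdeModel` and run
  the identical pipeline.

* Parameter inventories of the two case studies (name, description,
  ranked-or-excluded) shipped as CSV, for bookkeeping and for exercising
  the exclusion machinery at realistic parameter counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .ode_core import OdeModel, PiecewiseConstant

__all__ = [
    "ParameterInventory",
    "InventoryEntry",
    "make_linear_chain",
    "make_negative_feedback_oscillator",
    "make_cascade",
    "load_parameter_inventory",
    "MODEL_REGISTRY",
    "get_model",
    "count_local_maxima",
]


# ---------------------------------------------------------------------------
# analytic oracle

def make_linear_chain(k: float = 1.0, d: float = 0.5) -> OdeModel:
    """One-state production–degradation model dx/dt = k - d*x, x(0) = 0.

    The solution x(t) = (k/d)(1 - e^{-dt}) is linear in the production rate
    k, so multiplying k by alpha scales the whole output trajectory by
    alpha and the sensitivity index is exactly S = alpha - 1.  This makes
    the model the closed-form oracle for the randomized ranking: the mean
    index for k equals E[alpha] - 1.
    """
    if k <= 0 or d <= 0:
        raise ValidationError(f"rates must be positive, got k={k}, d={d}")

    def rhs(t, y, p, u):
        return [p["k"] - p["d"] * y[0]]

    return OdeModel(
        name="linear_chain",
        state_names=["x"],
        param_names=["k", "d"],
        nominal_params={"k": float(k), "d": float(d)},
        rhs=rhs,
        initial_state=np.array([0.0]),
        output_variable="x",
    )


# ---------------------------------------------------------------------------
# oscillatory negative-feedback surrogate (p53/Mdm2-like loop topology)

_OSC_DEFAULTS = {
    "p53_prod": 1.0,           # basal p53 production [conc/time]
    "p53_deg": 0.1,            # spontaneous p53 turnover [1/time]
    "mdm2_dependent_deg": 4.0, # Mdm2-mediated p53 removal [1/(conc*time)]
    "mdm2_transcription": 2.0, # p53-driven inhibitor mRNA synthesis [conc/time]
    "mdm2_mrna_deg": 0.7,      # inhibitor mRNA turnover [1/time]
    "mdm2_translation": 2.0,   # inhibitor protein synthesis per mRNA [1/time]
    "mdm2_deg": 0.7,           # inhibitor protein turnover [1/time]
    "hill_K": 0.3,             # transcription half-activation level [conc]
    "hill_n": 4.0,             # transcription cooperativity [-]
}


def make_negative_feedback_oscillator(params: Mapping[str, float] | None = None) -> OdeModel:
    """Three-state oscillator: protein -> inhibitor mRNA -> inhibitor protein.

    The output protein (p53-like) induces transcription of its own
    inhibitor (Mdm2-like) through a cooperative Hill term, and the
    inhibitor removes the protein bilinearly — a delayed negative feedback
    loop that, at the frozen defaults, produces repeated pulses of the
    output over the default horizon.  Reducing either inhibitor-production
    parameter (transcription or translation) weakens the feedback and
    raises the output AUC, mirroring the direction of the Mdm2-targeting
    interventions studied on the real pathway.  Illustrative surrogate
    only; see the module docstring.
    """
    p = dict(_OSC_DEFAULTS)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ValidationError(f"unknown oscillator parameters: {sorted(unknown)}")
        p.update({k: float(v) for k, v in params.items()})

    def rhs(t, y, pm, u):
        p53, mrna, mdm2 = y
        hill = p53 ** pm["hill_n"] / (pm["hill_K"] ** pm["hill_n"] + p53 ** pm["hill_n"]) if p53 > 0 else 0.0
        return [
            pm["p53_prod"] - pm["p53_deg"] * p53 - pm["mdm2_dependent_deg"] * mdm2 * p53,
            pm["mdm2_transcription"] * hill - pm["mdm2_mrna_deg"] * mrna,
            pm["mdm2_translation"] * mrna - pm["mdm2_deg"] * mdm2,
        ]

    return OdeModel(
        name="negative_feedback",
        state_names=["p53", "mdm2_mrna", "mdm2"],
        param_names=list(p),
        nominal_params=p,
        rhs=rhs,
        initial_state=np.zeros(3),
        output_variable="p53",
        non_ranked_params=frozenset({"hill_K", "hill_n"}),
    )


# ---------------------------------------------------------------------------
# aperiodic cascade surrogate (JAK/STAT-like receptor -> kinase -> transcript)

_CASCADE_DEFAULTS = {
    "receptor_activation": 0.5,   # ligand-driven receptor activation [1/time]
    "receptor_deactivation": 0.2, # receptor shutdown [1/time]
    "stat_phos": 1.0,             # receptor-driven STAT-like phosphorylation [1/time]
    "stat_dephos": 0.5,           # phosphatase-mediated reversal [1/time]
    "transcript_prod": 1.0,       # transcription per active factor [conc/time]
    "transcript_deg": 0.3,        # transcript turnover [1/time]
}


def make_cascade(params: Mapping[str, float] | None = None) -> OdeModel:
    """Aperiodic signaling cascade driven by a constant stimulation input.

    A cytokine-like excitation activates a receptor pool, the active
    receptor phosphorylates a transcription factor (STAT-like), and the
    active factor drives production of the output transcript, which decays
    first-order.  The response rises monotonically to a plateau (at most
    one local maximum).  Reducing the phosphorylation rate suppresses the
    transcript (S < 0); reducing the transcript degradation rate stabilises
    it and amplifies the response (S > 0) — the two drug directions the
    method is meant to distinguish on the real cytokine pathway.
    Illustrative surrogate only; see the module docstring.
    """
    p = dict(_CASCADE_DEFAULTS)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ValidationError(f"unknown cascade parameters: {sorted(unknown)}")
        p.update({k: float(v) for k, v in params.items()})

    def rhs(t, y, pm, u):
        r, s, m = y
        return [
            pm["receptor_activation"] * u * (1.0 - r) - pm["receptor_deactivation"] * r,
            pm["stat_phos"] * r * (1.0 - s) - pm["stat_dephos"] * s,
            pm["transcript_prod"] * s - pm["transcript_deg"] * m,
        ]

    return OdeModel(
        name="cascade",
        state_names=["receptor_active", "stat_active", "transcript"],
        param_names=list(p),
        nominal_params=p,
        rhs=rhs,
        initial_state=np.zeros(3),
        output_variable="transcript",
        excitation=PiecewiseConstant([0.0], [1.0]),  # constant stimulation
    )


#: registry for configuration files and the CLI ``--model`` flag
MODEL_REGISTRY: dict[str, Callable[[], OdeModel]] = {
    "linear_chain": make_linear_chain,
    "negative_feedback": make_negative_feedback_oscillator,
    "cascade": make_cascade,
}

#: a sensible default horizon per registered model (overridable in config)
DEFAULT_HORIZONS = {
    "linear_chain": 10.0,
    "negative_feedback": 100.0,
    "cascade": 50.0,
}


def get_model(name: str) -> OdeModel:
    """Instantiate a registered demonstration model with default parameters."""
    try:
        factory = MODEL_REGISTRY[name]
    except KeyError:
        raise ValidationError(
            f"unknown model {name!r}; registered models: {sorted(MODEL_REGISTRY)}"
        ) from None
    return factory()


def count_local_maxima(x: np.ndarray, min_prominence: float = 1e-6) -> int:
    """Strict interior local maxima of a sampled signal (peak detector)."""
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(np.asarray(x, dtype=float), prominence=min_prominence)
    return int(peaks.size)


# ---------------------------------------------------------------------------
# case-study parameter inventories

@dataclass(frozen=True)
class InventoryEntry:
    index: int
    name: str
    description: str
    ranked: bool


@dataclass
class ParameterInventory:
    """Parameter bookkeeping table of one case-study pathway model."""

    model_label: str
    entries: list[InventoryEntry]

    def __post_init__(self) -> None:
        idx = [e.index for e in self.entries]
        names = [e.name for e in self.entries]
        if sorted(idx) != list(range(1, len(idx) + 1)):
            raise ValidationError(f"{self.model_label}: indices not contiguous from 1")
        if len(set(names)) != len(names):
            raise ValidationError(f"{self.model_label}: duplicate parameter names")

    @property
    def ranked_names(self) -> list[str]:
        return [e.name for e in self.entries if e.ranked]

    @property
    def excluded_names(self) -> list[str]:
        return [e.name for e in self.entries if not e.ranked]

    def __getitem__(self, index: int) -> InventoryEntry:
        for e in self.entries:
            if e.index == index:
                return e
        raise KeyError(index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])


_INVENTORY_FILES = {
    "p53": "p53_parameters.csv",
    "jakstat": "jakstat_parameters.csv",
}


def load_parameter_inventory(label: str) -> ParameterInventory:
    """Load a case-study inventory ('p53' or 'jakstat') from the bundled CSV."""
    try:
        fname = _INVENTORY_FILES[label]
    except KeyError:
        raise ValidationError(
            f"unknown inventory {label!r}; available: {sorted(_INVENTORY_FILES)}"
        ) from None
    with resources.files("aucsens.data").joinpath(fname).open("r") as fh:
        df = pd.read_csv(fh)
    entries = [
        InventoryEntry(
            index=int(r["index"]), name=str(r["name"]),
            description=str(r["description"]), ranked=bool(r["ranked"]),
        )
        for r in df.to_dict("records")
    ]
    return ParameterInventory(model_label=label, entries=entries)
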