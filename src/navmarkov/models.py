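"""The shipped Nav1.5 gating models and their default parameters.

Two schemes are packaged as human-readable YAML definition files (so the
wiring can be revised without touching code):

* ``model_I``  — 8 states: closed C1→C2→C3, open O, fast-inactivated
  I11–I14.  Activation runs along the closed ladder (α1–α3 forward,
  β1–β2 backward, with the O→C3 deactivation rate β3 derived from
  microscopic reversibility of the scheme's single reaction cycle); fast
  inactivation enters from O into I14 (ρ2) and recovery runs
  I14→I13→I12→I11→C1 with the final I11→C1 step (φ1) rate limiting.
* ``model_II`` — Model I plus slow-inactivated I21–I24: prolonged
  depolarization moves occupancy slowly from the fast-inactivated row into
  the slow row (two-step inactivation), producing bi-exponential recovery.

The default parameter set is packaged alongside and is shared by both
models.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .scheme import KineticScheme, ModelParameters

__all__ = [
    "default_parameters",
    "load_scheme",
    "build_model_I",
    "build_model_II",
    "PARAMETER_NAMES",
]

#: every named entry the packaged schemes reference
PARAMETER_NAMES = (
    "alpha1", "alpha2", "alpha3", "beta1", "beta2",
    "phi1", "phi2", "phi3", "rho1", "rho2", "rho3", "c",
)


def _data_text(filename: str) -> str:
    return resources.files("navmarkov.data").joinpath(filename).read_text()


def default_parameters() -> ModelParameters:
    """The packaged best-fit parameter set (shared by both models)."""
    return ModelParameters(yaml.safe_load(_data_text("default_params.yaml")))


def load_scheme(name_or_path) -> KineticScheme:
    """Load a packaged scheme (``model_I`` / ``model_II``) or a scheme file."""
    if name_or_path in ("model_I", "model_II"):
        return KineticScheme.from_dict(yaml.safe_load(_data_text(f"{name_or_path}.yaml")))
    path = Path(name_or_path)
    if not path.exists():
        raise FileNotFoundError(
            f"unknown model {name_or_path!r}: not a packaged scheme and not a file"
        )
    return KineticScheme.from_file(path)


def _check_complete(scheme: KineticScheme, params: ModelParameters) -> KineticScheme:
    missing = [n for n in PARAMETER_NAMES if n not in params]
    if missing:
        raise KeyError(f"parameter set is missing entries: {missing}")
    scheme.generator(params, -120.0)  # bind every law once
    return scheme


def build_model_I(params: ModelParameters | None = None) -> KineticScheme:
    """The 8-state fast-inactivation model (validated against ``params``)."""
    return _check_complete(load_scheme("model_I"), params or default_parameters())


def build_model_II(params: ModelParameters | None = None) -> KineticScheme:
    """The 12-state two-step (fast + slow) inactivation model."""
    return _check_complete(load_scheme("model_II"), params or default_parameters())
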