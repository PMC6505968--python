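"""Model registry and simulation core."""

from .core import ModelDefinition, ParameterSpec, SimulationError, simulate, simulate_batch, steady_state
from .minibrain import CAL, FITTABLE, VesselWallParams, minibrain_model, muscular_tension
from .toy import ToyModelParams, toy_model, toy_simulate

_REGISTRY = {
    "toy": toy_model,
    "minibrain": minibrain_model,
}


def get_model(name: str) -> ModelDefinition:
    """Look up a bundled model by name ('toy' or 'minibrain')."""
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: {sorted(_REGISTRY)}") from None


__all__ = [
    "ModelDefinition", "ParameterSpec", "SimulationError", "simulate",
    "simulate_batch", "steady_state", "minibrain_model", "muscular_tension",
    "VesselWallParams", "toy_model", "toy_simulate", "ToyModelParams",
    "get_model", "CAL", "FITTABLE",
]
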