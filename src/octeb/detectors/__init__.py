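"""The three boundary detectors compared in the benchmark.

Each detector maps a preprocessed B-scan to a boolean edge map of the
same shape.  ``get_detector`` resolves a name ("canny", "twopass",
"edgeflow") to its parameter class and callable, which is what the
benchmark runner and the CLI use.
"""

from .canny import CannyParams, canny, gradient_field
from .edgeflow import (
    EdgeFlowParams,
    edgeflow_detect,
    edgeflow_direction,
    edgeflow_energy,
    edgeflow_vector,
    propagate_flow,
)
from .twopass import (
    TwoPassParams,
    two_pass_detect,
    two_pass_kernel,
    two_pass_passes,
    two_pass_responses,
)

__all__ = [
    "CannyParams", "canny", "gradient_field",
    "TwoPassParams", "two_pass_kernel", "two_pass_responses",
    "two_pass_passes", "two_pass_detect",
    "EdgeFlowParams", "edgeflow_energy", "edgeflow_direction",
    "edgeflow_vector", "propagate_flow", "edgeflow_detect",
    "DETECTORS", "get_detector",
]

#: name -> (parameter class, detect callable)
DETECTORS = {
    "canny": (CannyParams, canny),
    "twopass": (TwoPassParams, two_pass_detect),
    "edgeflow": (EdgeFlowParams, edgeflow_detect),
}


def get_detector(name: str):
    """Resolve a detector name to (param_class, detect_function)."""
    try:
        return DETECTORS[name]
    except KeyError:
        raise ValueError(
            f"unknown detector {name!r}; available: {sorted(DETECTORS)}"
        ) from None
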