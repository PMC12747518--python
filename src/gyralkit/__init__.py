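"""gyralkit: cortical folding by differential growth, and the morphometry
to compare the folded surfaces.

The package covers the full in-silico arm of a comparative gyrification
study: synthesize smooth brain-like solids, fold them by simulating
differential tangential growth of a soft bilayer (multiplicative
morphoelastic decomposition, neo-Hookean energy, explicit quasi-static
relaxation with self-contact), then quantify the folded surfaces with
shape-index morphometry and compare them through landmark-matched
quasi-conformal disk maps and a p-norm similarity index.
"""

from .types import (
    LandmarkCurve,
    ScalarField,
    TetVolume,
    TriSurface,
    ValidationReport,
)

__version__ = "0.1.0"


def __getattr__(name):
    # lazy access to the heavier submodule surfaces
    import importlib

    for mod in ("synth", "io", "growth", "morphometry", "diskmap", "similarity", "pipeline"):
        module = importlib.import_module(f".{mod}", __name__)
        if name in getattr(module, "__all__", ()):
            return getattr(module, name)
    raise AttributeError(f"module 'gyralkit' has no attribute {name!r}")


__all__ = [
    "TriSurface",
    "TetVolume",
    "LandmarkCurve",
    "ScalarField",
    "ValidationReport",
    "__version__",
]
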