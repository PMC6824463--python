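"""oristress: replication-origin firing, damage-mapping, QFA and plasmid
topology analysis for budding-yeast replication-checkpoint studies.

Subpackages follow the stages of the analysis: :mod:`oristress.synthetic`
generates ground-truth data; :mod:`oristress.profiling` turns S/G1 coverage
into replication profiles and origin calls; :mod:`oristress.damage` maps
replication-normalized DNA-damage signal by gene orientation;
:mod:`oristress.qfa` scores quantitative-fitness screens;
:mod:`oristress.plasmid` summarizes plasmid loss and catenation;
:mod:`oristress.io`, :mod:`oristress.config` and :mod:`oristress.pipeline`
hold the file formats, configuration and end-to-end driver.
"""

from .core import GeneAnnotation, GenomicTrack, Origin, ValidationError

__version__ = "0.1.0"

__all__ = ["GenomicTrack", "Origin", "GeneAnnotation", "ValidationError", "__version__"]


def __getattr__(name):
    # lazy submodule access: oristress.profiling etc. without eager imports
    import importlib

    if name in {
        "synthetic", "profiling", "damage", "qfa", "plasmid",
        "io", "config", "pipeline", "cli",
    }:
        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
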