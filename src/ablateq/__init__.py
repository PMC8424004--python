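"""In-silico planning of atrial-fibrillation ablation with deep Q-learning.

The package couples a Fenton–Karma monodomain simulator of 2D left-atrial
tissue (with patchy fibrosis and pulmonary-vein holes) to an episodic
reinforcement-learning environment in which an agent places 9x9-pixel
catheter-ablation lesions to terminate re-entrant rotors, and a deep
Q-network that learns lesion-placement policies from image observations.
"""

from . import tissue, fenton_karma, rotors

__all__ = ["tissue", "fenton_karma", "rotors", "env", "nn", "agent", "orchestrate"]
__version__ = "0.1.0"


def __getattr__(name):  # lazy: heavier modules only on demand
    if name in ("env", "nn", "agent", "orchestrate"):
        import importlib

        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(name)
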