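"""Pluggable SCF engine registry.

The response code is engine-agnostic: anything that maps
(atoms, charge, multiplicity, method, restricted, guess_mix) to a
:class:`~nearsight.qm.moset.MOSet` can be registered.  The built-in
Kohn-Sham solver ships as ``"internal"`` and is the default.
"""

from __future__ import annotations

from typing import Callable

from .moset import MOSet
from .scf import Method, run_scf as _internal_scf

_ENGINES: dict[str, Callable[..., MOSet]] = {"internal": _internal_scf}


class EngineNotRegisteredError(KeyError):
    pass


def register_engine(name: str, fn: Callable[..., MOSet]) -> None:
    """Register an external electronic-structure adapter under ``name``."""
    _ENGINES[name] = fn


def available_engines() -> list[str]:
    return sorted(_ENGINES)


def run_scf(
    atoms,
    charge: int = 0,
    multiplicity: int = 1,
    method: Method = Method(),
    restricted: bool = True,
    engine: str = "internal",
    guess_mix: float = 0.0,
) -> MOSet:
    """Run the registered engine ``engine`` and return its converged MOSet."""
    if engine not in _ENGINES:
        raise EngineNotRegisteredError(
            f"engine {engine!r} is not registered; available: {available_engines()}"
        )
    return _ENGINES[engine](
        atoms, charge=charge, multiplicity=multiplicity, method=method,
        restricted=restricted, guess_mix=guess_mix,
    )
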