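"""Model parameters.

A single frozen dataclass carries every knob of the family/society model:
the intrinsic growth rate ``b``, the cultural mutation scale ``mu``, the
similarity tolerance ``tau``, the demographic sizes ``N_f`` (initial
families per society) and ``N_s`` (societies in the system), and the two
selection pressures ``d_c`` (mortality increase from lack of cooperation)
and ``d_m`` (mortality increase from mating competition), plus run
controls.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the multi-level kinship model.

    Defaults are the standard simulation conditions: ``b=5.0``, ``mu=0.1``,
    ``tau=1.0``, ``N_f=N_s=50``; ``d_c`` and ``d_m`` are the environmental
    pressures that are varied between experiments.
    """

    b: float = 5.0
    mu: float = 0.1
    tau: float = 1.0
    N_f: int = 50
    N_s: int = 50
    d_c: float = 0.0
    d_m: float = 0.0
    n_steps: int = 500
    seed: int = 0
    #: generations an individual may stay unmarried before dying childless
    unmarried_lifespan: int = 2
    #: a society splits when it reaches this factor times N_f families
    split_threshold_factor: float = 2.0
    #: marriage events are retained for the trailing this-many steps
    event_log_window: int = 10

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError("b must be > 0")
        if not self.tau > 0:
            raise ValueError("tau must be > 0")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.N_f < 2:
            raise ValueError("N_f must be >= 2")
        if self.N_s < 1:
            raise ValueError("N_s must be >= 1")
        if self.d_c < 0 or self.d_m < 0:
            raise ValueError("d_c and d_m must be >= 0")
        if self.unmarried_lifespan < 1:
            raise ValueError("unmarried_lifespan must be >= 1")
        if self.split_threshold_factor <= 0:
            raise ValueError("split_threshold_factor must be > 0")

    @property
    def split_threshold(self) -> int:
        """Family count at which a society splits in half."""
        return int(round(self.split_threshold_factor * self.N_f))

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
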