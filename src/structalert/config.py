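"""Run-time configuration: every distance cutoff and threshold of the pipeline.

Defaults are the relaxed cutoffs (standard interaction distances + 1 Å, which
compensates for side-chain modelling error and homology-model coordinate error).
``strict`` mode subtracts that 1 Å from the three interaction cutoffs.
"""

from __future__ import annotations

import dataclasses

RELAXED_EXTRA = 1.0  # Å added to the three standard interaction distances


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """All tunable thresholds of the structural-alert pipeline.

    Distances in Å, volumes in Å^3, SASA-derived quantities in percent.
    """

    mode: str = "relaxed"  # "relaxed" | "strict"

    # interactions
    disulfide_cutoff: float = 3.3
    hbond_cutoff: float = 3.9
    saltbridge_cutoff: float = 5.0

    # burial
    rsa_buried: float = 9.0        # RSA < 9% -> buried
    rsa_switch_delta: float = 5.0  # buried/exposed switch needs |dRSA| >= 5

    # clash
    clash_local_radius: float = 20.0
    clash_overlap: float = 0.4
    clash_score_min: float = 30.0
    clash_delta_min: float = 18.0

    # cavity
    cavity_probe_in: float = 1.4
    cavity_probe_out: float = 4.0
    cavity_grid: float = 0.6
    cavity_delta: float = 70.0

    # SASA
    sasa_probe: float = 1.4
    sasa_points: int = 960

    # cis-peptide omega window (degrees)
    cis_omega_max: float = 45.0

    # repacking
    repack_shell: float = 5.0      # neighbour shell stripped and repacked
    chi_grid_step: float = 15.0    # coarse chi search step
    chi_refine_step: float = 5.0   # local refinement step

    # sequence->structure mapping
    alignment_identity_floor: float = 30.0  # percent

    def __post_init__(self) -> None:
        if self.mode not in ("relaxed", "strict"):
            raise ValueError(f"mode must be 'relaxed' or 'strict', got {self.mode!r}")
        if self.mode == "strict":
            object.__setattr__(self, "disulfide_cutoff", self.disulfide_cutoff - RELAXED_EXTRA)
            object.__setattr__(self, "hbond_cutoff", self.hbond_cutoff - RELAXED_EXTRA)
            object.__setattr__(self, "saltbridge_cutoff", self.saltbridge_cutoff - RELAXED_EXTRA)


DEFAULT_CONFIG = RunConfig()
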