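"""Analysis-wide configuration.

All thresholds used across the pipeline live here so that a single object
can be echoed into reports and round-tripped through YAML configs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field


@dataclass
class AnalysisConfig:
    """Thresholds and numerical tolerances for the whole analysis.

    Parameters
    ----------
    growth_cutoff:
        Biomass flux (per hour) below which the in-silico organism is
        considered non-growing; metabolites whose blockade drops growth
        below this are called essential.
    medium_uptake_bound:
        Magnitude of the uptake bound applied to exchange reactions of
        medium components (flux units; applied as a lower bound of
        ``-medium_uptake_bound``).
    forced_uptake_min:
        Small non-zero lower bound placed on source reactions for
        metabolites observed to be imported, forcing solutions consistent
        with the qualitative uptake profile.
    flux_epsilon:
        A reaction/metabolite "can carry flux" iff the relevant optimum
        exceeds this threshold.
    consistency_epsilon:
        Flux-consistency threshold used by gap filling (blocked-reaction
        detection); deliberately larger than ``flux_epsilon``.
    lp_tolerance:
        Feasibility tolerance for LP solutions.
    bh_q:
        Benjamini-Hochberg false-discovery-rate level.
    chi2_alpha:
        Significance level for chi-square enrichment tests.
    rng_seed:
        Seed for any stochastic step.
    """

    growth_cutoff: float = 0.1
    medium_uptake_bound: float = 100.0
    forced_uptake_min: float = 0.01
    flux_epsilon: float = 1e-6
    consistency_epsilon: float = 1e-4
    lp_tolerance: float = 1e-9
    bh_q: float = 0.05
    chi2_alpha: float = 0.05
    rng_seed: int = 0
    presence_min_detected_offset: int = 1  # present iff k >= n - offset

    def __post_init__(self) -> None:
        for name in (
            "growth_cutoff",
            "medium_uptake_bound",
            "forced_uptake_min",
            "flux_epsilon",
            "consistency_epsilon",
            "lp_tolerance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("bh_q", "chi2_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


DEFAULT_CONFIG = AnalysisConfig()
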