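"""Shared phantom configurations for the example scripts."""

from ctvent import PhantomSpec
from ctvent.phantom import GaussianBump, VentilationPattern


def benefit_like_spec(seed: int = 42) -> PhantomSpec:
    """A patient whose tumor sits next to a hyper-ventilating region — the
    configuration that profits from functional avoidance."""
    return PhantomSpec(
        tumor_center_mm=(-18.0, 0.0, 10.0),
        tumor_radius_mm=10.0,
        ventilation_pattern=VentilationPattern(
            base_expansion=0.05,
            expansion_gradient=(0.0, 0.0, 4e-4),
            bumps=(GaussianBump((-18.0, 0.0, 32.0), 0.09, 26.0),),
        ),
        seed=seed,
    )
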