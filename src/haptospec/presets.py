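"""Published parameter presets for the invasion simulations.

Every preset shares the base coefficients dn = dm = 0.001, alpha = 0.1,
epsilon = 0.01 and varies the haptotaxis strength gamma, the ECM
degradation rate eta, and (for the proliferating variants) mu1, mu2 and
beta.  Preset names follow the figure numbering of the original
simulation study so runs are easy to cross-reference; figs 1/3/5 are the
basic Dirichlet model, figs 7-14 the proliferating variants with the two
MDE production laws, and fig15 the four-field inhibitor model.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import InvasionParameters, ModelVariant

__all__ = ["Preset", "PRESETS", "get_preset"]


@dataclass(frozen=True)
class Preset:
    name: str
    variant: ModelVariant
    params: InvasionParameters
    N: int


def _base(**kw: float) -> InvasionParameters:
    return InvasionParameters(dn=0.001, dm=0.001, alpha=0.1, epsilon=0.01, **kw)


_V = ModelVariant

PRESETS: dict[str, Preset] = {
    p.name: p
    for p in (
        Preset("fig1", _V.BASIC_DIRICHLET, _base(gamma=0.005, eta=10.0, beta=0.0), 30),
        Preset("fig3", _V.BASIC_DIRICHLET, _base(gamma=0.01, eta=10.0, beta=0.0), 30),
        Preset("fig5", _V.BASIC_DIRICHLET, _base(gamma=0.02, eta=20.0, beta=0.0), 43),
        Preset("fig7", _V.PROLIFERATION,
               _base(gamma=0.005, eta=10.0, beta=0.07, mu1=0.1, mu2=0.5), 30),
        Preset("fig8", _V.PROLIFERATION,
               _base(gamma=0.005, eta=10.0, beta=0.07, mu1=0.5, mu2=0.1), 30),
        Preset("fig9", _V.SATURATING_MDE,
               _base(gamma=0.005, eta=10.0, beta=0.07, mu1=0.1, mu2=0.5), 30),
        Preset("fig10", _V.SATURATING_MDE,
               _base(gamma=0.005, eta=10.0, beta=0.07, mu1=0.5, mu2=0.1), 30),
        Preset("fig11", _V.PROLIFERATION,
               _base(gamma=0.01, eta=10.0, beta=0.07, mu1=0.1, mu2=0.5), 30),
        Preset("fig12", _V.PROLIFERATION,
               _base(gamma=0.01, eta=10.0, beta=0.07, mu1=0.5, mu2=0.1), 30),
        Preset("fig13", _V.SATURATING_MDE,
               _base(gamma=0.01, eta=10.0, beta=0.07, mu1=0.1, mu2=0.5), 30),
        Preset("fig14", _V.SATURATING_MDE,
               _base(gamma=0.01, eta=10.0, beta=0.07, mu1=0.5, mu2=0.1), 30),
        Preset("fig15", _V.INHIBITOR,
               _base(gamma=0.005, eta=10.0, beta=0.07, mu1=0.5, mu2=0.1,
                     du=0.001, theta=0.05, xi=0.03, rho=0.07), 30),
    )
}

#: snapshot times discussed alongside the published figures
DEFAULT_SNAPSHOT_TIMES = (0.0, 1.0, 2.0, 10.0, 20.0)


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESETS)}"
        ) from None
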