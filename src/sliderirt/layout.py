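"""Naming and ordering of the latent person-parameter vector.

The joint model stacks three person parameters (VAS location ``theta_V``,
DRS location ``theta_D``, DRS width ``eta_D``) for every trait and
occasion, ordered occasion-major: all first-occasion dimensions, then
all second-occasion dimensions.  With two traits and two occasions this
is the 12-vector

    theta_V_E_1, theta_D_E_1, eta_D_E_1, theta_V_C_1, theta_D_C_1,
    eta_D_C_1,  theta_V_E_2, ... , eta_D_C_2
"""

from __future__ import annotations

from typing import Sequence

PARAMS = ("theta_V", "theta_D", "eta_D")


def latent_label(param: str, trait: str, occasion: int) -> str:
    return f"{param}_{trait}_{occasion}"


def parse_label(label: str) -> tuple[str, str, int]:
    param, trait, occ = label.rsplit("_", 2)
    return param, trait, int(occ)


def latent_labels(
    traits: Sequence[str],
    occasions: Sequence[int],
    params: Sequence[str] = PARAMS,
) -> list[str]:
    """Ordered latent dimension labels, occasion-major then trait."""
    return [
        latent_label(p, t, o) for o in occasions for t in traits for p in params
    ]
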