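"""Symbolic re-derivation of the closed-form solutions.

The sample-tilt and knife-tilt closed forms were originally obtained by
computer algebra from the forward kinematics product and the
vertical-plane constraint.  This module repeats that derivation with
SymPy at import-free runtime, so a build-time test can confirm that the
implemented closed forms agree term-by-term with what the forward
kinematics actually implies — guarding against sign or typographical
errors in the transcribed formulas.
"""

from __future__ import annotations

import sympy as sp

__all__ = [
    "symbolic_forward",
    "derived_tilt_tangent",
    "implemented_tilt_tangent",
    "derived_knife_tangent",
    "implemented_knife_tangent",
    "verify_closed_forms",
]

# setup angles and machine angles (radians, symbolic)
th_T, th_R, th_IT, th_IK, th_to, th_tr = sp.symbols(
    "theta_T theta_R theta_IT theta_IK theta_to theta_tr", real=True
)

#: the setup constants in terms of the four setup angles
CONSTANTS = {
    "A": sp.cos(th_IK + th_to),
    "B": sp.sin(th_tr) * sp.sin(th_IK + th_to),
    "C": sp.sin(th_IT) * sp.sin(th_IK + th_to),
    "D": sp.cos(th_IT) * sp.sin(th_IK + th_to),
    "E": sp.cos(th_tr) * sp.sin(th_IK + th_to),
    "F": sp.sin(th_IT) * sp.cos(th_tr),
    "G": sp.sin(th_tr) * sp.cos(th_IT),
    "H": sp.sin(th_IT) * sp.sin(th_tr),
    "I": sp.cos(th_IT) * sp.cos(th_tr),
}


def _rot(axis: str, a):
    c, s = sp.cos(a), sp.sin(a)
    if axis == "x":
        return sp.Matrix([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return sp.Matrix([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    return sp.Matrix([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def symbolic_forward() -> sp.Matrix:
    """F = Rx(th_T) Ry(th_R) Rx(-th_IT) Rz(th_IK) Rz(th_to) Rx(th_tr)."""
    return (
        _rot("x", th_T)
        * _rot("y", th_R)
        * _rot("x", -th_IT)
        * _rot("z", th_IK)
        * _rot("z", th_to)
        * _rot("x", th_tr)
    )


def _c345():
    A, E, F, G, H, I = (CONSTANTS[k] for k in "AEFGHI")
    return A * I + H, E, A * F - G  # C3, C4, C5


def derived_tilt_tangent():
    """tan(theta_T) obtained by solving the verticality constraint
    (F yhat) . zhat = 0 for theta_T, in terms of the setup angles."""
    Fm = symbolic_forward()
    yhat = sp.Matrix([0, 1, 0])
    constraint = (Fm * yhat)[2]  # z-component of the transformed normal
    # linear in sin/cos(theta_T): a*sin(T) + b*cos(T) = 0 -> tan(T) = -b/a
    expanded = sp.expand_trig(constraint).expand()
    a = expanded.coeff(sp.sin(th_T))
    b = expanded.coeff(sp.cos(th_T))
    residual = sp.simplify(expanded - a * sp.sin(th_T) - b * sp.cos(th_T))
    if residual != 0:
        raise AssertionError("constraint is not linear in sin/cos(theta_T)")
    return sp.simplify(-b / a)


def implemented_tilt_tangent():
    """The implemented closed form, C1 cos(theta_R) + C2 sin(theta_R),
    with the constants expanded to the setup angles."""
    C3, C4, C5 = _c345()
    return (C5 * sp.cos(th_R) - C4 * sp.sin(th_R)) / C3


def derived_knife_tangent():
    """tan(theta_K) from the geometric definition
    ((yhat x F yhat) . zhat) / (yhat . F yhat), with the tilt solution
    substituted for theta_T on the principal branch."""
    Fm = symbolic_forward()
    yhat = sp.Matrix([0, 1, 0])
    fy = Fm * yhat
    num = yhat.cross(fy)[2]
    den = (yhat.T * fy)[0]
    t = implemented_tilt_tangent()
    # principal branch of arctan: cos(theta_T) = 1/sqrt(1+t^2)
    subs = {
        sp.sin(th_T): t / sp.sqrt(1 + t**2),
        sp.cos(th_T): 1 / sp.sqrt(1 + t**2),
    }
    expr = sp.expand_trig(num).expand().subs(subs) / sp.expand_trig(den).expand().subs(subs)
    return expr


def implemented_knife_tangent():
    """The implemented closed form
    C3 (C4 cos + C5 sin) / (sqrt(C3^2 + (C4 sin - C5 cos)^2) |C3|),
    with the constants expanded to the setup angles."""
    C3, C4, C5 = _c345()
    c, s = sp.cos(th_R), sp.sin(th_R)
    return C3 * (C4 * c + C5 * s) / (sp.sqrt(C3**2 + (C4 * s - C5 * c) ** 2) * sp.Abs(C3))


def verify_closed_forms() -> bool:
    """Confirm both implemented closed forms agree with the re-derivation.

    Returns True when both differences simplify to zero; raises
    AssertionError otherwise.
    """
    dt = sp.simplify(derived_tilt_tangent() - implemented_tilt_tangent())
    if dt != 0:
        raise AssertionError(f"sample-tilt closed form mismatch: {dt}")
    dk = sp.simplify(derived_knife_tangent() - implemented_knife_tangent())
    if dk != 0:
        raise AssertionError(f"knife-tilt closed form mismatch: {dk}")
    return True
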