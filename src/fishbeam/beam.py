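"""Euler–Bernoulli prediction of subregion strain from curvature.

Under plane-sections beam kinematics with the vertebral column as the
neutral axis, a longitudinal fibre at signed transverse offset gamma from a
column bent to curvature kappa carries longitudinal strain

    epsilon = -kappa * gamma

per plane of bending: positive dorsoventral curvature (dorsiflexion,
concave dorsal) shortens dorsally offset muscle, and positive mediolateral
curvature (concave left) shortens leftward-offset muscle.  With biplanar
flexion the per-plane predictions add:

    epsilon_total(t) = -kappa_dv(t, x_bar) * gamma_dv
                       - kappa_ml(t, x_bar) * gamma_ml

evaluated at the subregion's resting longitudinal position x_bar.  The
sagittal curvature must be baseline-corrected first so that predicted strain
is referenced to the same resting state as the measured strain.
"""

from __future__ import annotations

from .curvature import CurvatureField
from .datatypes import ValidationError
from .strain import StrainSeries, SubregionGeometry


def predicted_strain(field: CurvatureField, geom: SubregionGeometry,
                     ) -> dict[str, StrainSeries]:
    """Predict a subregion's strain from curvature at its resting position.

    Returns the per-plane and total predictions keyed ``"predicted_dv"``,
    ``"predicted_ml"``, ``"predicted_total"``.  Curvature is evaluated at the
    resting x_bar for all frames; the subregion is not tracked along the
    column as it deforms.
    """
    if not field.baseline_corrected["dv"]:
        raise ValidationError(
            "sagittal curvature must be baseline-corrected before predicting "
            "strain (resting column curvature would read as resting strain)")
    kdv, kml = field.at(geom.x_bar)
    eps_dv = -kdv * geom.gamma_dv
    eps_ml = -kml * geom.gamma_ml
    return {
        "predicted_dv": StrainSeries(eps_dv, "predicted_dv", geom.pair),
        "predicted_ml": StrainSeries(eps_ml, "predicted_ml", geom.pair),
        "predicted_total": StrainSeries(eps_dv + eps_ml, "predicted_total",
                                        geom.pair),
    }
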