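"""End-to-end conversion: SBML text in, complete symbolic dataset out."""

from __future__ import annotations

from .conservation_laws import (
    conservation_constraints,
    dynamic_species_indices,
    left_kernel_basis,
)
from .crnt_metrics import classify, deficiency
from .exporters import Dataset
from .network_model import build_network, kinetic_matrix, stoichiometric_matrix
from .ode_assembly import assemble_odes, build_name_map
from .sbml_ingest import (
    SupportReport,
    check_supported,
    inline_all,
    lift_local_parameters,
    parse_sbml,
)

__all__ = ["UnsupportedModelError", "convert", "PIPELINE_STAGES"]

PIPELINE_STAGES = (
    "parse",
    "inline-functions",
    "lift-locals",
    "gate",
    "network",
    "name-map",
    "ode-assembly",
    "conservation",
    "crnt",
    "classify",
)


class UnsupportedModelError(Exception):
    """The document uses features outside the supported set."""

    def __init__(self, report: SupportReport):
        self.report = report
        items = "; ".join(f"{f} ({e})" for f, e, _ in report.violations)
        super().__init__(f"unsupported model: {items}")


def convert(
    document: str | bytes,
    source: str = "",
    compartment_division: bool = True,
    log=None,
) -> Dataset:
    """Run the full conversion pipeline on an SBML document.

    Raises :class:`UnsupportedModelError` (with the itemized
    :class:`~odelift.sbml_ingest.SupportReport`) when gating fails, and the
    ingest errors for malformed input.  ``log`` is an optional callable
    receiving stage names.
    """
    stage = log or (lambda name: None)
    stage("parse")
    model = parse_sbml(document)
    stage("inline-functions")
    model = inline_all(model)
    stage("lift-locals")
    model = lift_local_parameters(model)
    stage("gate")
    report = check_supported(model)
    if not report.supported:
        raise UnsupportedModelError(report)
    stage("network")
    net = build_network(model)
    S = stoichiometric_matrix(net)
    Kin = kinetic_matrix(net)
    stage("name-map")
    nm = build_name_map(net)
    stage("ode-assembly")
    ode = assemble_odes(net, model, nm, compartment_division=compartment_division)
    stage("conservation")
    dyn = dynamic_species_indices(net)
    S_dyn = S[dyn, :] if dyn else S[0:0, :]
    basis = left_kernel_basis(S_dyn)
    laws, constraints = conservation_constraints(
        basis, dyn, net, ode.initial_values, nm
    )
    ode.constraints.extend(constraints)
    stage("crnt")
    report_def = deficiency(net)
    stage("classify")
    classification = classify(net, ode)
    return Dataset(
        ode_system=ode,
        stoich=S,
        kinetic=Kin,
        conservation=tuple(laws),
        deficiency=report_def,
        classification=classification,
        source=source,
        model_id=model.model_id,
    )
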