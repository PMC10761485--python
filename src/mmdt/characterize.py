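"""Patient stratification: derive the similarity measures with full provenance.

The three matching measures (fitness, high-risk cytogenetics, ISS stage) are
evaluated through the recursive operator engine so that every instantiation
yields a trace of which observed factors fed which operators.
"""

from __future__ import annotations

from .engine import EvaluationContext, OperatorRegistry, TraceGraph, evaluate
from .knowledge import EntityNetwork
from .reference import SIMILARITY_TARGETS
from .scores import SimilarityFeatures
from .values import ClinicalValue


def derive_similarity_features(observations: dict[str, ClinicalValue],
                               registry: OperatorRegistry,
                               network: EntityNetwork) -> tuple[SimilarityFeatures, TraceGraph]:
    """Evaluate fitness, high-risk cytogenetics and ISS stage for one patient.

    ``observations`` must already be unit-normalized (see
    :func:`mmdt.io.read_patient`).  Returns the features together with the
    provenance trace of the instantiation.
    """
    context = EvaluationContext(observations=dict(observations))
    results = {target: evaluate(target, context, registry, network)
               for target in SIMILARITY_TARGETS}

    iss_value = results["iss_stage"].as_category()
    features = SimilarityFeatures(
        fitness=results["fitness"].as_category(),
        high_risk_cytogenetics=results["high_risk_cytogenetics"].as_tristate(),
        iss_stage=None if iss_value is None else int(iss_value),
    )
    return features, context.trace
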