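"""Shared test helpers."""

from trialcea.synthetic import GeneratorConfig


def symmetric_config(**overrides) -> GeneratorConfig:
    """Two arms drawn from identical distributions (null configuration)."""
    base = dict(
        baseline_ids_mean_sd=((43.0, 11.0), (43.0, 11.0)),
        group_effect=0.0,
        group_cost_effect=0.0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)
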