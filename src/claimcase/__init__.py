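"""claimcase: rule-based case ascertainment over administrative claims.

Subpackages/modules:

- :mod:`claimcase.model` — cohort domain types and CSV I/O
- :mod:`claimcase.codesets` — diagnosis-code / specialty classification
- :mod:`claimcase.engine` — algorithm representation, evaluation and DSL
- :mod:`claimcase.stats` — diagnostic-accuracy measures, CIs, ranking
- :mod:`claimcase.simulate` — seeded synthetic cohort generator
- :mod:`claimcase.cli` — pipeline orchestration and command-line interface
"""

from importlib import resources

__version__ = "0.1.0"


def data_path(name: str):
    """Path to a bundled data file (code_config.yaml, algorithms.json,
    validation_tables.csv)."""
    return resources.files("claimcase").joinpath("data", name)
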