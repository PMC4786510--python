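"""Bundled fixtures: the 10-patient worked-example table and two ontologies."""

from importlib import resources
from pathlib import Path

__all__ = [
    "example_table_path",
    "example_ontology_path",
    "risk_factor_ontology_path",
]


def _path(name: str) -> Path:
    return Path(resources.files(__name__) / name)


def example_table_path() -> Path:
    """CSV of the 10-record, 5-feature worked-example dataset."""
    return _path("table2.csv")


def example_ontology_path() -> Path:
    """Override-based relatedness fixture for the 5 worked-example features."""
    return _path("example5.onto")


def risk_factor_ontology_path() -> Path:
    """Gastric-cancer risk-factor ontology covering the full 29-feature schema."""
    return _path("gastric_risk_factors.onto")
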