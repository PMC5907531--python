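"""Reading and writing parameter sets.

Parameter files are YAML key-value text::

    scheme: mmodel1
    isoform: hERG1a
    temperature_K: 296.15
    rates:
      ae: {alpha: 3.39e-2, beta: 1.04e-2}
      ...

Optional ``corr_a``/``corr_b`` entries carry correction factors.  Four
fixtures are shipped covering {mmodel1, mmodel2} x {hERG1a, hERG1b} at
room temperature; constrained transitions (the I -> C1 edge of
mmodel2) are never stored, they are derived at load/simulation time by
loop closure.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .errors import ValidationError
from .rates import RateLaw
from .scheme import ParameterSet, get_scheme

ISOFORMS = ("hERG1a", "hERG1b")
_FIXTURES = {
    ("mmodel1", "hERG1a"): "mmodel1_herg1a.yaml",
    ("mmodel1", "hERG1b"): "mmodel1_herg1b.yaml",
    ("mmodel2", "hERG1a"): "mmodel2_herg1a.yaml",
    ("mmodel2", "hERG1b"): "mmodel2_herg1b.yaml",
}


def _parse(doc: dict, origin: str) -> ParameterSet:
    for key in ("scheme", "isoform", "rates"):
        if key not in doc:
            raise ValidationError(f"{origin}: missing required key {key!r}")
    scheme = get_scheme(str(doc["scheme"]))
    rates: dict[str, RateLaw] = {}
    for name, entry in doc["rates"].items():
        if not isinstance(entry, dict) or "alpha" not in entry:
            raise ValidationError(f"{origin}: rate {name!r} must map alpha (and beta)")
        alpha = float(entry["alpha"])
        if alpha <= 0:
            raise ValidationError(f"{origin}: transition {name!r} has non-positive alpha")
        try:
            rates[name] = RateLaw(
                alpha=alpha,
                beta=float(entry.get("beta", 0.0)),
                corr_a=float(entry.get("corr_a", 1.0)),
                corr_b=float(entry.get("corr_b", 1.0)),
            )
        except ValidationError as exc:
            raise ValidationError(f"{origin}: transition {name!r}: {exc}") from None
    params = ParameterSet(
        scheme_name=scheme.name,
        isoform=str(doc["isoform"]),
        rates=rates,
        temperature=float(doc.get("temperature_K", 296.15)),
    )
    params.validate_against(scheme)
    return params


def load_parameters(source: str | Path) -> ParameterSet:
    """Load and validate a parameter file.

    Raises
    ------
    ValidationError
        Missing transitions, non-positive alpha, or unknown scheme,
        naming the offending entry.
    """
    path = Path(source)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValidationError(f"{path}: malformed YAML: {exc}") from None
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: expected a mapping at top level")
    return _parse(doc, str(path))


def load_builtin_parameters(scheme: str, isoform: str) -> ParameterSet:
    """Load one of the four shipped parameter sets.

    ``scheme`` is 'mmodel1' or 'mmodel2'; ``isoform`` is 'hERG1a' or
    'hERG1b' (case-insensitive, 'a'/'b' shorthands accepted).
    """
    iso = {"a": "hERG1a", "b": "hERG1b"}.get(isoform.lower(), isoform)
    iso = {i.lower(): i for i in ISOFORMS}.get(iso.lower())
    if iso is None:
        raise ValidationError(f"unknown isoform {isoform!r}; expected one of {ISOFORMS}")
    key = (scheme, iso)
    if key not in _FIXTURES:
        raise ValidationError(f"no shipped parameters for scheme {scheme!r}")
    ref = resources.files("hergkin.data").joinpath(_FIXTURES[key])
    doc = yaml.safe_load(ref.read_text())
    return _parse(doc, _FIXTURES[key])


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set in the same YAML layout the loader reads."""
    doc = {
        "scheme": params.scheme_name,
        "isoform": params.isoform,
        "temperature_K": params.temperature,
        "rates": {
            name: {
                "alpha": law.alpha,
                "beta": law.beta,
                **({"corr_a": law.corr_a} if law.corr_a != 1.0 else {}),
                **({"corr_b": law.corr_b} if law.corr_b != 1.0 else {}),
            }
            for name, law in sorted(params.rates.items())
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
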