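"""Data model of the OMERACT PsAMRIS hand instrument.

PsAMRIS grades six inflammatory and destructive features of psoriatic
arthritis — synovitis (0–3), flexor tenosynovitis (0–3), periarticular
inflammation (0/1), bone edema (0–3), bone erosion (0–10) and bone
proliferation (0/1) — in the metacarpophalangeal (MCP), proximal (PIP)
and distal (DIP) interphalangeal joints of digits 2–5.  Every joint is
read at two sites (proximal/distal bone or dorsal/palmar aspect,
depending on the feature), so the full instrument enumerates
12 joints x 2 sites x 6 features = 144 ordinal items whose sum is the
overall score.

A reduced instrument (e.g. sPsAMRIS, restricted to the joints most
responsive to change) is the same :class:`ScoreSchema` type restricted
to a joint subset, which keeps all downstream analytics schema-generic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import total_ordering
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

__all__ = [
    "SchemaError",
    "FeatureDef",
    "JointId",
    "JointSite",
    "ScoreSchema",
    "ItemValidation",
    "build_full_schema",
    "build_reduced_schema",
    "enumerate_items",
    "max_total_score",
    "validate_item",
    "save_schema",
    "load_schema",
    "load_bundled_schema",
    "as_joint",
    "canonical_site",
    "JOINT_ROWS",
    "DIGITS",
    "SITES",
    "FEATURE_NAMES",
]

JOINT_ROWS = ("MCP", "PIP", "DIP")
DIGITS = (2, 3, 4, 5)

#: Canonical site tokens.  Site A is the proximal (or dorsal) aspect,
#: site B the distal (or palmar) aspect; the anatomical alias pair in
#: use depends on the feature being read, so storage is abstract.
SITES = ("site_A", "site_B")
SITE_ALIASES = {
    "site_a": "site_A",
    "site_b": "site_B",
    "proximal": "site_A",
    "dorsal": "site_A",
    "distal": "site_B",
    "palmar": "site_B",
}
SITE_DISPLAY = {"site_A": ("proximal", "dorsal"), "site_B": ("distal", "palmar")}

FEATURE_NAMES = (
    "synovitis",
    "flexor_tenosynovitis",
    "periarticular_inflammation",
    "bone_edema",
    "bone_erosion",
    "bone_proliferation",
)
_FEATURE_MAX = {
    "synovitis": 3,
    "flexor_tenosynovitis": 3,
    "periarticular_inflammation": 1,
    "bone_edema": 3,
    "bone_erosion": 10,
    "bone_proliferation": 1,
}


class SchemaError(ValueError):
    """Raised for malformed instrument definitions or tokens."""


@dataclass(frozen=True)
class FeatureDef:
    """One scored feature with its ordinal range (score_min is always 0)."""

    name: str
    score_max: int
    score_min: int = 0

    def __post_init__(self) -> None:
        if self.name not in FEATURE_NAMES:
            raise SchemaError(
                f"unknown feature {self.name!r}; expected one of {FEATURE_NAMES}"
            )
        if self.score_min != 0:
            raise SchemaError(f"feature {self.name}: score_min must be 0")
        if self.score_max < self.score_min:
            raise SchemaError(f"feature {self.name}: empty score range")


def default_features() -> tuple[FeatureDef, ...]:
    """The six PsAMRIS features with their printed ranges, in reading order."""
    return tuple(FeatureDef(name, _FEATURE_MAX[name]) for name in FEATURE_NAMES)


@total_ordering
@dataclass(frozen=True)
class JointId:
    """A small hand joint: row (MCP/PIP/DIP) and digit (2–5).

    Joints are totally ordered anatomically — MCP < PIP < DIP, then digit
    ascending — and this ordering is the global tie-break and
    serialization order everywhere in the package.
    """

    row: str
    digit: int

    def __post_init__(self) -> None:
        if self.row not in JOINT_ROWS:
            raise SchemaError(f"unknown joint row {self.row!r}; expected one of {JOINT_ROWS}")
        if self.digit not in DIGITS:
            raise SchemaError(f"joint digit {self.digit} outside 2–5")

    @property
    def token(self) -> str:
        return f"{self.row}{self.digit}"

    @property
    def sort_key(self) -> tuple[int, int]:
        return (JOINT_ROWS.index(self.row), self.digit)

    def __lt__(self, other: "JointId") -> bool:
        return self.sort_key < other.sort_key

    def __str__(self) -> str:  # pragma: no cover - display convenience
        return self.token

    @classmethod
    def parse(cls, token: Union[str, "JointId"]) -> "JointId":
        if isinstance(token, JointId):
            return token
        text = str(token).strip().upper()
        row, digits = text[:3], text[3:]
        if row not in JOINT_ROWS or not digits.isdigit():
            raise SchemaError(f"cannot parse joint token {token!r} (expected e.g. 'MCP3')")
        return cls(row, int(digits))


def as_joint(value: Union[str, JointId]) -> JointId:
    return JointId.parse(value)


def canonical_site(token: str) -> str:
    """Resolve a site token or anatomical alias to 'site_A'/'site_B'."""
    key = str(token).strip().lower()
    if key not in SITE_ALIASES:
        raise SchemaError(f"unknown site token {token!r}; expected one of "
                          f"{SITES + ('proximal', 'distal', 'dorsal', 'palmar')}")
    return SITE_ALIASES[key]


@dataclass(frozen=True)
class JointSite:
    """One scored sub-region of a joint (two per joint)."""

    joint: JointId
    site: str

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise SchemaError(f"site must be canonical ({SITES}), got {self.site!r}")

    @property
    def token(self) -> str:
        return f"{self.joint.token}/{self.site}"


@dataclass(frozen=True)
class ScoreSchema:
    """An instrument definition: joints x sites x features.

    Both the full 12-joint PsAMRIS and any joint-restricted variant
    (sPsAMRIS) are values of this type; ``item_count`` is
    |joints| * sites_per_joint * |features|.
    """

    name: str
    joints: tuple[JointId, ...]
    features: tuple[FeatureDef, ...]
    sites_per_joint: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "joints", tuple(as_joint(j) for j in self.joints))
        object.__setattr__(self, "features", tuple(self.features))
        if not self.joints:
            raise SchemaError("schema must contain at least one joint")
        if len(set(self.joints)) != len(self.joints):
            raise SchemaError("duplicate joints in schema")
        if not self.features:
            raise SchemaError("schema must contain at least one feature")
        if len({f.name for f in self.features}) != len(self.features):
            raise SchemaError("duplicate features in schema")
        if not 1 <= self.sites_per_joint <= len(SITES):
            raise SchemaError("sites_per_joint must be 1 or 2")

    # -- derived views ----------------------------------------------------
    @property
    def sites(self) -> tuple[str, ...]:
        return SITES[: self.sites_per_joint]

    @property
    def joint_tokens(self) -> tuple[str, ...]:
        return tuple(j.token for j in sorted(self.joints))

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    @property
    def item_count(self) -> int:
        return len(self.joints) * self.sites_per_joint * len(self.features)

    def feature(self, name: str) -> FeatureDef:
        for f in self.features:
            if f.name == name:
                return f
        raise SchemaError(f"feature {name!r} not in schema {self.name!r}")

    def __contains__(self, joint: Union[str, JointId]) -> bool:
        try:
            return as_joint(joint) in set(self.joints)
        except SchemaError:
            return False


def build_full_schema(name: str = "PsAMRIS") -> ScoreSchema:
    """The full 12-joint / 24-site / 6-feature instrument (144 items)."""
    joints = tuple(JointId(row, digit) for row in JOINT_ROWS for digit in DIGITS)
    return ScoreSchema(name=name, joints=joints, features=default_features())


def build_reduced_schema(
    base: ScoreSchema,
    joints: Iterable[Union[str, JointId]],
    name: str = "reduced",
) -> ScoreSchema:
    """Restrict ``base`` to a joint subset; features and sites unchanged.

    Restriction composes: reducing twice equals reducing once to the
    final subset.  Joint order of the result follows ``base``.
    """
    wanted = {as_joint(j) for j in joints}
    if not wanted:
        raise SchemaError("reduced schema needs a non-empty joint set")
    unknown = wanted - set(base.joints)
    if unknown:
        tokens = ", ".join(j.token for j in sorted(unknown))
        raise SchemaError(f"joints not in base schema {base.name!r}: {tokens}")
    kept = tuple(j for j in base.joints if j in wanted)
    return ScoreSchema(name=name, joints=kept, features=base.features,
                       sites_per_joint=base.sites_per_joint)


def enumerate_items(schema: ScoreSchema) -> list[tuple[JointSite, FeatureDef]]:
    """All scored items in canonical order.

    Ordering is anatomical joint order, then site_A before site_B, then
    feature order as defined in the schema; length equals
    ``schema.item_count`` and two calls yield identical sequences.
    """
    items: list[tuple[JointSite, FeatureDef]] = []
    for joint in sorted(schema.joints):
        for site in schema.sites:
            for feature in schema.features:
                items.append((JointSite(joint, site), feature))
    return items


def max_total_score(schema: ScoreSchema) -> int:
    """Maximum attainable overall sum score (504 for full PsAMRIS)."""
    return sum(feature.score_max for _, feature in enumerate_items(schema))


@dataclass(frozen=True)
class ItemValidation:
    """Outcome of validating one (joint, site, feature, value) record."""

    ok: bool
    message: str = ""


def validate_item(
    schema: ScoreSchema,
    joint: Union[str, JointId],
    site: str,
    feature: str,
    value: int,
) -> ItemValidation:
    """Check one record against the schema; returns a violation, never raises."""
    try:
        jid = as_joint(joint)
    except SchemaError as exc:
        return ItemValidation(False, f"invalid joint token {joint!r}: {exc}")
    if jid not in set(schema.joints):
        return ItemValidation(False, f"joint {jid.token} not in schema {schema.name!r}")
    try:
        canon = canonical_site(site)
    except SchemaError as exc:
        return ItemValidation(False, str(exc))
    if canon not in schema.sites:
        return ItemValidation(False, f"site {canon} not scored in schema {schema.name!r}")
    if feature not in schema.feature_names:
        return ItemValidation(False, f"unknown feature {feature!r} for schema {schema.name!r}")
    fdef = schema.feature(feature)
    try:
        ivalue = int(value)
    except (TypeError, ValueError):
        return ItemValidation(False, f"value {value!r} is not an integer")
    if ivalue != float(value):
        return ItemValidation(False, f"value {value!r} is not an integer")
    if not fdef.score_min <= ivalue <= fdef.score_max:
        return ItemValidation(
            False,
            f"{feature} value {ivalue} out of range "
            f"{fdef.score_min}–{fdef.score_max}",
        )
    return ItemValidation(True)


# -- JSON serialization ---------------------------------------------------

def schema_to_dict(schema: ScoreSchema) -> dict:
    return {
        "name": schema.name,
        "sites_per_joint": schema.sites_per_joint,
        "joints": [j.token for j in schema.joints],
        "features": [
            {"name": f.name, "score_min": f.score_min, "score_max": f.score_max}
            for f in schema.features
        ],
    }


def schema_from_dict(doc: dict) -> ScoreSchema:
    try:
        features = tuple(
            FeatureDef(f["name"], int(f["score_max"]), int(f.get("score_min", 0)))
            for f in doc["features"]
        )
        return ScoreSchema(
            name=str(doc["name"]),
            joints=tuple(as_joint(j) for j in doc["joints"]),
            features=features,
            sites_per_joint=int(doc.get("sites_per_joint", 2)),
        )
    except KeyError as exc:
        raise SchemaError(f"schema document missing key {exc}") from exc


def save_schema(schema: ScoreSchema, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(json.dumps(schema_to_dict(schema), indent=2, sort_keys=True) + "\n")
    return path


def load_schema(path: Union[str, Path]) -> ScoreSchema:
    return schema_from_dict(json.loads(Path(path).read_text()))


def load_bundled_schema(name: str) -> ScoreSchema:
    """Load a shipped instrument document: 'psamris_full' or 'spsamris'."""
    ref = resources.files("psamris") / "schemas" / f"{name}.json"
    try:
        text = ref.read_text()
    except FileNotFoundError as exc:
        raise SchemaError(f"no bundled schema named {name!r}") from exc
    return schema_from_dict(json.loads(text))
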