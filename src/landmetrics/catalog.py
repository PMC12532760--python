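"""Class catalogs: mapping integer raster codes to land-cover classes.

A catalog declares, for every code that may appear in a raster, whether the
class is water (ocean or inland water) and whether it is a land class whose
metrics are reported.  Ocean gets its own flag because grid cells that are
entirely ocean in every year are removed from the landscape grid, while
inland-water windows are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ClassDef:
    code: int
    name: str
    is_water: bool = False
    is_ocean: bool = False
    is_land: bool = True

    def __post_init__(self):
        if self.is_ocean and not self.is_water:
            raise ValueError(f"class {self.name}: is_ocean implies is_water")
        if self.is_water and self.is_land:
            raise ValueError(f"class {self.name}: water classes are not land classes")


@dataclass
class ClassCatalog:
    """Ordered collection of :class:`ClassDef`, keyed by integer code."""

    classes: list[ClassDef] = field(default_factory=list)

    def __post_init__(self):
        codes = [c.code for c in self.classes]
        if len(codes) != len(set(codes)):
            raise ValueError("duplicate class codes in catalog")
        self._by_code = {c.code: c for c in self.classes}

    def __contains__(self, code: int) -> bool:
        return code in self._by_code

    def __getitem__(self, code: int) -> ClassDef:
        return self._by_code[code]

    def __iter__(self):
        return iter(self.classes)

    @property
    def codes(self) -> list[int]:
        return [c.code for c in self.classes]

    @property
    def land_codes(self) -> list[int]:
        return [c.code for c in self.classes if c.is_land]

    @property
    def water_codes(self) -> list[int]:
        return [c.code for c in self.classes if c.is_water]

    @property
    def ocean_codes(self) -> list[int]:
        return [c.code for c in self.classes if c.is_ocean]

    def name_of(self, code: int) -> str:
        return self._by_code[code].name


def hildaplus_catalog() -> ClassCatalog:
    """Catalog mirroring the HILDA+ v2b class scheme (six land classes,
    ocean plus inland water)."""
    return ClassCatalog(
        [
            ClassDef(11, "urban"),
            ClassDef(22, "cropland"),
            ClassDef(33, "pasture_rangeland"),
            ClassDef(44, "forest"),
            ClassDef(55, "grass_shrubland"),
            ClassDef(66, "sparse_no_vegetation"),
            ClassDef(77, "water", is_water=True, is_land=False),
            ClassDef(0, "ocean", is_water=True, is_ocean=True, is_land=False),
        ]
    )


def synthetic_catalog(n_land: int, ocean_code: int = 0) -> ClassCatalog:
    """Catalog for synthetic scenarios: land classes coded 1..n plus ocean."""
    defs = [ClassDef(ocean_code, "ocean", is_water=True, is_ocean=True, is_land=False)]
    defs += [ClassDef(i, f"class_{i}") for i in range(1, n_land + 1)]
    return ClassCatalog(defs)
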