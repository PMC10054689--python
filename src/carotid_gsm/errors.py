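"""Exception hierarchy shared across the pipeline."""


class CarotidGsmError(Exception):
    """Base class for all package errors."""


class DegeneratePolygonError(CarotidGsmError):
    """Polygon has fewer than 3 vertices."""


class EmptyRegionError(CarotidGsmError):
    """A region mask contains no pixels."""


class NonDiscriminatingReferencesError(CarotidGsmError):
    """Adventitia reference is not brighter than the lumen reference.

    Signals a bad annotation: the two-point brightness normalization
    needs the adventitia median to exceed the lumen median.
    """


class InsufficientDataError(CarotidGsmError):
    """Too few observations for the requested statistic."""


class SpecError(CarotidGsmError):
    """Invalid synthetic-data specification."""


class SeparationError(CarotidGsmError):
    """Logistic model shows (quasi-)complete separation."""
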