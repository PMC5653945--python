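"""Exception hierarchy shared across the pipeline.

All errors derive from :class:`OsteofractError` so callers can catch the
package's failures without masking programming errors.
"""


class OsteofractError(Exception):
    """Base class for all package errors."""


class InputError(OsteofractError):
    """A file could not be read or decoded."""


class ValidationError(OsteofractError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(OsteofractError, ValueError):
    """The input is formally valid but the operation is undefined on it
    (constant image under Otsu, tumor mask covering the whole frame, ...).

    Callers that can record the result as missing should catch this and do
    so; it is never silently swallowed inside the package.
    """
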