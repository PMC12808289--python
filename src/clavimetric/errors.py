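"""Exception hierarchy with stable CLI exit codes.

Exit codes: 0 success, 2 configuration, 3 en-face alignment failure,
4 segmentation/measurement consistency, 5 I/O and file-format problems.
"""

from __future__ import annotations


class ClavimetricError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(ClavimetricError):
    """Invalid or incomplete pipeline configuration.

    ``violations`` holds the exhaustive list of individual problems so a
    user can fix them all in one pass.
    """

    exit_code = 2

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class FormatError(ClavimetricError):
    """Unreadable or unsupported image file."""

    exit_code = 5


class IOFailure(ClavimetricError):
    """Filesystem problem (unwritable output directory, missing path)."""

    exit_code = 5


class ValidationError(ClavimetricError):
    """Input data violates an invariant (e.g. inconsistent DICOM spacing)."""

    exit_code = 2


class GeometryError(ClavimetricError):
    """Degenerate or mismatched geometry (lattice mismatch, zero-length centerline)."""

    exit_code = 4


class BoundsError(ClavimetricError):
    """Region of interest outside the grid, or empty."""

    exit_code = 2


class LabelError(ClavimetricError):
    """Requested label or role absent/empty in a label grid."""

    exit_code = 4


class SeedError(ClavimetricError):
    """Seed point outside the grid or outside the threshold mask."""

    exit_code = 4


class AlignmentError(ClavimetricError):
    """En-face alignment check failed."""

    exit_code = 3


class ConsistencyError(ClavimetricError):
    """Measured quantities are mutually impossible (e.g. negative epiphysis volume)."""

    exit_code = 4


class PhantomSpecError(ClavimetricError):
    """Invalid synthetic-phantom specification."""

    exit_code = 2
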