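"""Exception types raised by fusdwi operations."""


class FusdwiError(Exception):
    """Base class for all fusdwi errors."""


class InvalidGeometryError(FusdwiError):
    """Phantom geometry is inconsistent (e.g. lesion extends outside the brain)."""


class DegenerateImageError(FusdwiError):
    """No usable cutoff intensity exists (e.g. constant image)."""


class NoLesionFoundError(FusdwiError):
    """Thresholding produced an empty supra-cutoff voxel set."""


class EmptyROIError(FusdwiError):
    """A region of interest contains no valid voxels."""


class DegenerateVarianceError(FusdwiError):
    """Paired differences have zero variance but nonzero mean."""


class InsufficientDataError(FusdwiError):
    """Too few diffusion volumes to determine the tensor."""


class UnsupportedShellStructureError(FusdwiError):
    """Gradient table has more than one nonzero b-value shell."""


class FormatError(FusdwiError):
    """On-disk files are mutually inconsistent (e.g. volume/gradient count mismatch)."""
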