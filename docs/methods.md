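# Methods

This note documents the models, conventions and numerical choices behind
crowdvol, and what the synthetic studies do and do not demonstrate.

## Coordinate conventions

Volumes are `(z, y, x)`-indexed, 0-based, with *y* increasing downward
(raster convention). Pixel `(i, j)` — column *i*, row *j* — has its centre
at continuous coordinates `(i + 0.5, j + 0.5)`; slice *z* spans
`[z, z + 1)` in depth, so a point "on slice z" carries the voxel-centre
coordinate `z + 0.5`. Intensities are floats internally; 8-bit export
quantizes once, by round-half-up, so preprocessing chains do not
accumulate quantization error.

## Subject geometry

A tiling plan for tile size *t* and overlap fraction *f* uses stride
`s = t·(1−f)` and pads the image by `t − s` per side; tile origins advance
by *s*, and the final origin is clamped so the last tile flushes the padded
edge (coverage may duplicate, it never truncates). At the default
`f = 0.5` the pad equals the stride, every original pixel is covered by two
tiles per axis (four in 2D), and a pixel within `s/2` of one tile's edge is
at least `s/2` from every edge of some other tile — the property that
rescues features cut by tile boundaries. `pixel_multiplicity()` reports the
per-pixel coverage so an operator can reduce the retirement limit in
proportion; the tool reports, it does not decide.

Flipbooks take `2h + 1` consecutive slices (default `h = 2`, a five-image
stack) annotated on the central plane, with `annotation_frame_index = h`.
Centers closer than *h* to the stack ends are refused rather than clamped:
annotation quality is known to degrade where context runs out, so short
stacks must be an explicit operator decision. Striding the volume in *z*
distorts z-scale; the stride is recorded in the manifest and undone when
marks are mapped back (`z = z_subject + (frame − h)·z_stride`).

Encoded subject sizes are validated against a 600 KB recommendation and a
1 MB hard cap (warn in `[600 KB, 1 MB)`, error at `≥ 1 MB`); frames are
encoded as lossless 8-bit PNG by default.

## Export parsing

The export dialect (README) is frozen as this tool's contract. Contributor
names are pseudonymized on ingest with a stable salted hash (`h:` + 12 hex
digits); the hash is idempotent on its own output so simulated exports
round-trip exactly. Anonymous rows take their identity from a `session`
column when present, otherwise each such row is its own pseudo-contributor
— collapsing unknown people into one voter would corrupt vote counts.
Workflow versions compare numerically per dotted component (10.1 > 2.3).
Malformed rows are rejected with a reason and counted, never dropped:
`#parsed + #rejected = #rows` always. Per (contributor, subject, workflow)
only the earliest classification is kept; ties break on the lowest
classification id.

## Question consensus and early retirement

Majority voting with a deterministic lexicographic tie-break, ties flagged
so analysts can exclude them. Early retirement uses the lead-versus-
remaining criterion — retire when
`(top − second) > (N − votes cast)` — the weakest condition that still
guarantees no completion of the vote can change the unique winner, for any
number of answer choices. For unanimous prefixes this triggers at
`⌊N/2⌋ + 1` votes (three of five). The test suite verifies safety by
exhaustive enumeration of completions for limits up to 7 and up to 4
choices; a tie after completion counts as "outcome altered".

## Point consensus

DBSCAN is written out from its definition — core point: at least
`min_samples` neighbours within `eps`, inclusive and counting itself;
clusters: connected components of core points under eps-adjacency plus
border points attached to the first core that reaches them; the rest is
noise — rather than delegated to a library, so its behaviour is fully
specified and testable against an independent brute-force oracle. Defaults
when aggregating: `eps` should be set to the expected object radius (an
operator decision), `min_samples = ⌈N/2⌉` mirroring majority logic, and
the z-distance scale factor to the manifest's `z_stride`. Cluster support
counts distinct contributors, so a volunteer double-marking an object
cannot promote it. Ellipse marks contribute their centres; semi-axes are
retained on the record for bounding-box style exports. HDBSCAN is not
provided; DBSCAN is the single clustering backend.

## Contour consensus (CRIA)

Strokes are closed when their endpoint gap is at most the closure
tolerance (default 5% of the frame diagonal) by appending the first
vertex; strokes with larger gaps or fewer than three distinct vertices are
rejected and reported, never guessed at. Interiors are rasterized under
the even-odd rule at pixel centres — chosen because volunteer freehand
strokes self-intersect, and even-odd is deterministic and orientation-
independent there. One contributor's multiple loops on a frame are OR-ed
before counting, so the height map's *N* counts contributors, not strokes.

The consensus keeps pixels with `2·height ≥ N` — "half or more",
inclusive. With even *N* this includes exact-half pixels; at `N = 2` the
consensus is the union of both interiors. This follows from taking the
half threshold inclusively, and is deliberate. Raising the threshold above
one half can only shrink the region (monotonicity, tested). An alternative
reading — thresholding at the mean of observed heights rather than at
`N/2` — was considered and not implemented; the half-or-more rule is the
implemented semantics throughout.

Outlier removal is a single two-pass scheme: provisional consensus over
all masks (or an expert mask when available) as reference, masks with IoU
below the cutoff (default 0.3) excluded, consensus recomputed once on the
survivors. If the cutoff would exclude everyone, all masks are kept and
the result flagged rather than silently emptied. Iterating exclusion to a
fixed point was considered and rejected: one pass is predictable and
sufficient for the gross (spam-level) outliers the cutoff targets.

Consensus masks are re-vectorized by tracing pixel-corner boundary loops;
re-rasterizing the loops with XOR (even-odd across loops) reproduces the
mask bit-for-bit, holes included, because pixel centres at half-integer
coordinates never coincide with the integer-coordinate traced edges.

## Assembly

Marks map to global coordinates via
`(x, y) = tile origin + local − padding`; marks landing in the padding
band (outside the original image) are flagged and excluded. Duplicate
detections across overlapping tiles merge by DBSCAN with
`min_samples = 1` at the merge radius (default: the aggregation `eps`),
with support-weighted mean centroids and support-weighted label votes.
Mask fusion averages the per-tile agreement fractions over all covering
tiles and thresholds at 0.5, which carries the "half or more" semantics
across tiles; a uniform mean is used rather than a coverage-weighted
threshold — coverage compensation for reduced retirement limits is left to
the operator. Voxels outside every tile stay unset.

## The simulator: what it emulates, and what it does not

Phantoms are noisy volumes (Gaussian background, σ = 0.05 of the intensity
scale, lightly smoothed) containing bright spherical objects packed by
rejection sampling with a `radius + 2` margin from every face, with
per-slice ground-truth boundary polygons. The volunteer model draws every
random quantity from a substream keyed by (seed, volunteer index, subject,
purpose), so adding volunteers or subjects never perturbs existing
annotations and every dataset replays bit-identically.

Error modes modelled, with the defaults used by the recovery studies:

- **Contours**: per-vertex radial Gaussian jitter, σ = 1 px; half of all
  strokes are left with a small endpoint gap to exercise loop closure.
- **Point marks**: in-plane Gaussian jitter, σ = 1 px, placed on the slice
  containing the object centre (`z = ⌊c_z⌋ + 0.5`). z is not continuously
  jittered: marks are made on a 2D canvas and the export format carries z
  only as an integer frame index, so continuous z error is not
  representable; the residual z error is bounded by half the slice
  spacing. Spurious marks arrive Poisson-distributed at 0.2 marks per true
  object per volunteer, placed away from every object.
- **Answers**: correct with probability 0.8, else uniform over the wrong
  choices.
- **Spam**: an annotation replaced by a scribble in the far corner of the
  frame; emitted closed half the time so both rejection paths (closure
  failure and IoU cutoff) are exercised.

Study conditions: question and contour studies use 5 volunteers (the
retirement-limit worked example); the marking study uses 10, reflecting
that drawing tasks run with higher retirement limits than single
questions, with `min_samples = 5`. Problem sizes: contour studies use a
radius-18 disk in a 64×64 frame over 20 seeds; point studies a 28×96×96
phantom with 4 objects over 20 seeds; the end-to-end study a 26×56×56
phantom with 2 objects, tiled 32×32 at 50% overlap, over 10 seeds.

What the simulator does **not** model: realistic EM/X-ray texture and
contrast, anisotropic voxels, volunteer skill variation or learning over
time, systematic inter-volunteer bias (e.g. everyone tracing slightly
outside a membrane), crowded scenes with stacked or touching objects, and
missing-wedge artefacts. Passing recovery tests therefore demonstrates
that the aggregation machinery recovers ground truth under idealized,
well-separated, unbiased noise — not that a real project with these
parameters will reach the same accuracy.

## Known limitations

- Orthogonal-slice subject generation (axial/sagittal/coronal resampling)
  is not implemented.
- No mesh or surface export; consensus is voxel/raster only.
- Stacked-object disambiguation beyond the label-vote cleaning pass is out
  of scope.
- Contributor-weighted or skill-modelled voting is not provided; all
  volunteers count equally.
- The fusion threshold is uniform across coverage levels.
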