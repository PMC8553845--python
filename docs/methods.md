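# Methods

## The measurement model

An apposition compound eye assigns each ommatidium a gaze direction; the
field of local angular steps between neighbouring ommatidia — the
interommatidial angle Δφ(azimuth, elevation) — is the quantity of interest.
The pseudopupil principle turns it into a kinematic measurement: the
pseudopupil marks the facets whose axes point at the observer, so rotating
the head by a known goniometer step (Δlat, Δlon) moves the pseudopupil
centre across the lattice by a number of facets inversely proportional to
the local Δφ.

Facet positions are expressed in axial ("facet-row") coordinates (u, v),
two axes at 60°, pitch 1 facet, with an orthogonal planar embedding
x = u + v/2, y = v·√3/2 used for all metric work. Which hexagonal row is
anatomically horizontal in a given species is *not* assumed: the estimator
works in the planar basis and the registration of image pixels to lattice
coordinates carries an explicit orientation angle, so the u-horizontal
convention is internal bookkeeping only.

At each node of the scanned grid the estimator forms the displacement
matrix

    M = [ ∂(x, y)/∂lon   ∂(x, y)/∂lat ]   (facets per degree)

by central differences at interior nodes and one-sided differences at
edges (edge nodes are flagged lower-confidence in all exports). Its inverse
J = M⁻¹ (degrees per facet) is the local angular step map:
Δφ_h = |J e_x|, Δφ_v = |J e_y|, Δφ_mean = (Δφ_h + Δφ_v)/2, and the
three-row average Δφ_3axis = mean_k |J a_k| over the three hexagonal axis
directions a_k. Δφ_mean is the primary map value; Δφ_3axis is always
computed and exported alongside, since the two conventions coexist in the
field and differ for anisotropic lattices. Nodes with missing observations
or singular M are flagged invalid, never interpolated. The quadrature
combination √(Δφ_h² + Δφ_v²) is exposed as `hex_combine`; note that a
*horizontal row separation* must be halved before use, because adjacent
rows are staggered by half a facet — the 2.6°/2 = 1.3° with 1.0° vertical
giving 1.64° is the canonical example.

A 10° goniometer step spans roughly five facets at Δφ ≈ 2°, so the finite
difference is intrinsically a local average over about a 5×5-facet rhomboid
of eye surface; no extra smoothing is applied (a 3×3 node median filter is
available but off by default). Consequently the recovered value at a node
is the *harmonic mean* of Δφ along the step — exact wherever the gaze field
is linear, slightly below the midpoint value where Δφ grows.

### Longitude foreshortening

On a spherical gaze chart a longitude step at latitude λ subtends an arc of
Δlon·cos λ. `build_map(..., cos_lat_correction=True)` divides the longitude
derivative by cos λ accordingly and should be used for goniometer data from
real eyes. The default is `False`: the synthetic generator (below) defines
its gaze field on a flat (azimuth, elevation) chart with no foreshortening,
and for such data the uncorrected estimator is the exact inverse — with the
correction enabled on chart data, recovered horizontal angles would be
biased by cos λ. The two conventions agree on the equator and on the
frontal meridian, which is where all headline map claims live.

## The synthetic eye (what it emulates, and what not)

The generator stands in for goniometer imagery of a real stained eye. Its
acuity field is piecewise linear:

    Δφ(az, el) = Δφ_min + s_az·max(|az|−w, 0)
               + s_d·max(el−w, 0) + s_v·max(−el−w, 0)

a flat acute-zone plateau of half-width w around the frontal axis with
independent lateral, dorsal and ventral fall-offs. The gaze field integrates
this per unit planar distance — elevation along the central column, azimuth
along each row — in closed form (the piecewise-linear reciprocal integrates
to logarithms), so observation generation inverts the gaze field exactly
rather than to an ODE tolerance. By construction the azimuth derivative
equals the local field value and the elevation derivative equals the
frontal-meridian value at that elevation; vertical acuity does not vary
with azimuth, a deliberate simplification.

The honeybee-forager preset (Δφ_min = 1.30°, w = 10°, s_az = 0.00875,
s_d = 0.10, s_v = 0.015 deg/deg) consists of *derived constants*, not
anatomical measurements: they are chosen so that harmonic-mean smoothing of
the 10°-step finite differences reproduces the forager acute-zone figures —
frontal minimum 1.30° exactly (the plateau covers the central difference
stencil), equatorial values ≤ 1.7° to 40° azimuth, ventral values ≤ 1.9°
to −30° elevation, > 2° by +20° elevation. Default scan: latitude −40..+40°,
longitude −10..+60°, 10° steps (72 poses); facet pitch 20 µm. Longitude is
a signed azimuth with no special treatment of the sagittal midline.

Centre-localization noise is zero-mean Gaussian in the planar facet
coordinates (detection error is a distance in facets, not in angle). All
randomness derives from a single integer seed.

Rendered frames are phenomenological: facet discs on the hexagonal mosaic,
fluorescent brightness exp(−θ²/2σ²) with θ the angular distance between
facet gaze and pose and σ = (180/π)·NA (the objective's acceptance
half-angle), dark mode as the inverted envelope broadened ×1.6; a Gaussian
imaging blur of half a facet pitch, saturated landmark facets for
registration, optional additive noise; 16-bit output. Frames default to
384×384 px at 2.5 µm/px (48 facet pitches) so the envelope decays before
the frame edge — min–max profile normalization on a truncated envelope
biases FWHM low. Not modelled: diffraction, corneal ray tracing,
screening-pigment spectra, eye curvature in the image, multiple
pseudopupils. Passing tests therefore validate the *analysis chain*
(detection → registration → differencing → inversion), not the optics of
any real cornea.

## Detection conventions

The centre estimator is a background-subtracted intensity centroid over the
connected component containing the global maximum, thresholded at
min + f·(max − min) with f = 0.5 by default; dark pupils are handled by
frame inversion. The estimator is affine-invariant and, on symmetric spots,
unbiased (a uniform-field eye recovers rendered centres to machine
precision). For the *broad* dark pseudopupil on a graded eye the
low-threshold centroid is biased by the acuity gradient across its wide
support — precisely the imprecision that motivates fluorescent staining —
so dark centres are located on the darkest core using f = 0.7; with that
convention fluorescent and dark centres of rendered pairs coincide to well
under 0.2 facet pitch at frontal poses. Profiles are min–max normalized
("relative pixel values"); FWHM interpolates the half-level crossings
nearest the peak; ties in peak position resolve to the smallest position.
Landmark correspondence (which blob is which lattice point) is assumed
given; the similarity registration is solved as a complex linear least
squares, degenerate only when fewer than two distinct landmarks exist.

## Numerical choices and edge cases

* Acute-zone summaries: the minimum is over valid nodes' Δφ_mean with ties
  resolved toward the frontal axis (smallest |elevation|, then |azimuth|,
  then signed values) — under the honeybee preset a one-sided edge node
  ties the frontal node exactly, and the frontal location is the meaningful
  acute-zone centre. Sub-threshold extents use threshold + 0.05° so a node
  numerically on the contour counts as inside.
* Displacement matrices are declared singular below |det| = 1e−9;
  Jacobians satisfy M·J = I to 1e−9.
* Recovery reports quote RMSE over interior nodes (one-sided edge
  differencing amplifies noise heavy-tailedly, and edge nodes are flagged);
  the all-node RMSE is reported alongside.
* Observation/map text formats use a fixed header and dot-decimal floats;
  parse errors carry line numbers. Invalid nodes serialize with empty angle
  cells and valid=0.
* Problem sizes: the default 72-pose scan, 384×384 px frames and the test
  suite's rendered-pair comparisons all run in seconds; they are the sizes
  at which the study conditions are fully expressed.

## Known limitations

Vertical acuity independent of azimuth in the generator; flat-chart gaze
geometry (no spherical curvature, hence no cross-term between the axes off
the meridians); phenomenological optics; no automatic landmark
correspondence or facet segmentation; binocular-overlap boundaries are not
computed. The recovered Δφ at strongly graded locations is a harmonic mean
over the goniometer step, and dorsal edge nodes under noise are the least
reliable part of any map.
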