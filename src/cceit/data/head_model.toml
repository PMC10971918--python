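# Geometric constraint tables for the numerical head phantom.
# Every sampled parameter is given as [mean, half_range]; samples are drawn
# within mean +- half_range (truncated normal by default, sd = half_range/2).
# Lengths in mm, angles in degrees. Negative "size" entries are additive
# offsets to the reference object's semiaxes; positive sizes are semiaxes.

[head]
semi_a = 77.0    # fixed outline, gives a 575 mm circumference
semi_b = 105.0

[shell]
skin_thickness = 3.0
skull_thickness = [7.5, 1.5]

[inner]                       # brain-bounding ellipse, relative to head
center_x = [-0.5, 2.5]
center_y = [-1.5, 4.5]
dsize_x = [-14.0, 5.0]
dsize_y = [-14.0, 5.0]
tilt = [2.0, 10.0]

[hemi.l_down]                 # relative to inner
center_x = [-25.5, 9.5]
center_y = [-21.5, 9.5]
dsize_x = [-23.5, 14.5]
dsize_y = [-50.0, 12.0]
tilt = [-72.5, 12.5]

[hemi.l_up]
center_x = [-24.5, 7.5]
center_y = [24.0, 10.0]
dsize_x = [-30.5, 7.5]
dsize_y = [-32.0, 9.0]
tilt = [-20.0, 22.0]

[hemi.r_down]
center_x = [25.5, 6.5]
center_y = [-20.0, 11.0]
dsize_x = [-25.5, 17.5]
dsize_y = [-54.5, 11.5]
tilt = [72.5, 11.5]

[hemi.r_up]
center_x = [27.0, 7.0]
center_y = [26.0, 13.0]
dsize_x = [-32.0, 9.0]
dsize_y = [-33.5, 7.5]
tilt = [29.0, 15.0]

[divider]                     # vertical line splitting the hemispheres
shift_x = [-3.0, 6.0]
shift_y = [-8.5, 10.5]
tilt = [1.0, 10.0]

[csf.center]                  # relative to inner
center_x = [0.5, 2.5]
center_y = [-2.5, 13.5]
dsize_x = [-54.5, 8.5]
dsize_y = [-53.0, 15.0]
tilt = [2.0, 9.0]

# Four CSF lobes placed on the central CSF ellipse boundary: "angle" is the
# axis angle from the vertical (+y) axis CCW, "shift" the distance along the
# outward normal from the boundary point to the lobe centre.

[csf.lobe1]
angle = [149.5, 10.5]
shift = [8.5, 1.5]
semi_a = [17.5, 2.5]
semi_b = [9.0, 1.0]
tilt = [-27.0, 6.0]

[csf.lobe2]
angle = [25.0, 23.0]
shift = [8.5, 1.5]
semi_a = [18.0, 2.0]
semi_b = [9.0, 1.0]
tilt = [22.0, 5.0]

[csf.lobe3]
angle = [-51.0, 11.0]
shift = [1.5, 4.5]
semi_a = [13.0, 5.0]
semi_b = [5.5, 2.5]
tilt = [5.5, 5.5]

[csf.lobe4]
angle = [-130.5, 13.5]
shift = [1.5, 4.5]
semi_a = [16.0, 5.0]
semi_b = [5.0, 2.0]
tilt = [-6.0, 6.0]

# Acceptance windows enforced by rejection sampling on every candidate.
# Area percentages are of the total image area; the hemisphere ratio is
# left/right x 100.

[limits]
inner_circumference = [487.5, 53.5]
inner_axes_ratio = [1.3, 0.2]
center_csf_circumference_ratio = [0.3, 0.1]
center_csf_axes_ratio = [4.4, 2.9]
lobe1_circumference = [93.5, 24.5]
lobe2_circumference = [94.0, 22.0]
lobe3_circumference = [57.0, 21.0]
lobe4_circumference = [70.0, 23.0]
brain_area_pct = [23.0, 6.0]
csf_area_pct = [23.0, 6.0]
rest_area_pct = [13.5, 5.5]
hemisphere_ratio_pct = [98.5, 7.5]

[image]
extent_mm = 208.0
raster_n = 128
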