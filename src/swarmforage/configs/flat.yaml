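# Flat environment: same footprint as the sloped arena, uniform speeds,
# no item sliding.  The zone markings remain but have no kinematic effect.
kind: arena
environment: flat
length: 9.75
width: 1.75
zone_lengths: [1.5, 2.5, 3.75, 2.0]
slope_angle: 0.0
n_source_items: 5
speed_flat: 0.15
speed_up: 0.15
speed_down: 0.15
item_slide_speed: 0.0
scale: 1.0
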