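# Synthetic approximation of a horticultural named-color chart (CIELAB, D65/2deg).
# The RHS colour chart itself is proprietary; these entries are this package's
# own documented approximations except Greyed-Purple 185-A, whose triple is the
# published reference value for reverted blackberry drupelets.  Users may supply
# their own table with the same columns (name, L, a, b).
name,L,a,b
White 155-D,96.0,-0.5,2.5
Yellow-White 158-A,92.0,-2.0,14.0
Yellow 9-A,86.0,2.0,78.0
Yellow-Orange 16-A,78.0,18.0,72.0
Orange 25-A,65.0,42.0,62.0
Orange-Red 30-A,54.0,58.0,48.0
Orange-Red 34-A,52.0,55.0,40.0
Red 42-A,48.0,62.0,34.0
Red 45-A,42.0,58.0,28.0
Red 46-A,38.0,56.0,24.0
Red 53-A,33.0,52.0,18.0
Red-Purple 59-A,30.0,44.0,4.0
Red-Purple 64-A,38.0,48.0,-2.0
Purple 77-A,34.0,30.0,-22.0
Purple-Violet 82-A,36.0,24.0,-32.0
Violet 86-A,32.0,12.0,-40.0
Violet-Blue 93-A,36.0,2.0,-44.0
Blue 100-A,36.0,-8.0,-38.0
Blue 104-B,62.0,-12.0,-28.0
Green 137-A,38.0,-24.0,22.0
Green 139-A,32.0,-20.0,18.0
Yellow-Green 144-A,60.0,-28.0,48.0
Yellow-Green 146-A,46.0,-18.0,34.0
Greyed-Yellow 160-A,74.0,4.0,30.0
Greyed-Orange 165-A,48.0,26.0,30.0
Greyed-Orange 172-A,44.0,34.0,28.0
Greyed-Red 178-A,36.0,38.0,16.0
Greyed-Red 180-A,40.0,32.0,14.0
Greyed-Purple 183-A,28.0,30.0,4.0
Greyed-Purple 185-A,34.4,42.0,12.7
Greyed-Purple 187-A,24.0,22.0,2.0
Greyed-Green 189-A,56.0,-10.0,8.0
Greyed-Green 191-A,44.0,-8.0,6.0
Brown 200-A,30.0,14.0,16.0
Black 202-A,12.0,2.0,0.0
Black 203-A,8.0,1.0,-1.0
Grey 201-B,55.0,0.0,0.0
Grey-Brown 199-A,34.0,8.0,10.0
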