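# Coarse Ramachandran region polygons for four residue classes.
# Schema: class <TAB> level <TAB> semicolon-separated "phi,psi" vertices (degrees,
# closed polygon, vertices in order).  level is "favored" or "allowed"; favored
# polygons are subsets of the union of allowed polygons; a point inside any
# favored polygon is favored, inside any allowed (or favored) polygon is allowed,
# otherwise it is an outlier.  These are deliberately coarse convex regions
# capturing the canonical alpha / beta / left-handed-alpha (and for proline the
# alpha / polyproline-II) basins; they are not a digitization of any published
# contour set and numerical agreement with MolProbity is not claimed.
general	favored	-170,90;-50,90;-50,180;-170,180
general	favored	-160,-75;-50,-75;-50,-10;-160,-10
general	favored	40,10;90,10;90,90;40,90
general	allowed	-180,60;-20,60;-20,180;-180,180
general	allowed	-180,-180;-45,-180;-45,-150;-180,-150
general	allowed	-180,-120;-20,-120;-20,45;-180,45
general	allowed	20,-20;105,-20;105,105;20,105
glycine	favored	-150,-90;-40,-90;-40,10;-150,10
glycine	favored	40,-10;150,-10;150,90;40,90
glycine	favored	-180,110;-40,110;-40,180;-180,180
glycine	favored	40,-180;180,-180;180,-110;40,-110
glycine	allowed	-180,-180;-30,-180;-30,180;-180,180
glycine	allowed	30,-180;180,-180;180,180;30,180
proline	favored	-90,-50;-40,-50;-40,-10;-90,-10
proline	favored	-90,110;-40,110;-40,180;-90,180
proline	allowed	-110,-75;-35,-75;-35,180;-110,180
preproline	favored	-170,90;-50,90;-50,180;-170,180
preproline	favored	-140,-60;-60,-60;-60,-20;-140,-20
preproline	allowed	-180,60;-20,60;-20,180;-180,180
preproline	allowed	-180,-80;-40,-80;-40,50;-180,50
preproline	allowed	20,-40;100,-40;100,100;20,100
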