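# synthetic wholemount counting record (200 sites, 10x10 um frame on a
# 320x320 um grid); per-site counts constructed so that sum(Q) = 8970
site_x_mm,site_y_mm,count
-1.2354,-2.3041,28
-0.9154,-2.3041,37
-0.5954,-2.3041,32
-0.2754,-2.3041,29
0.0446,-2.3041,35
0.3646,-2.3041,35
0.6846,-2.3041,49
1.0046,-2.3041,37
-1.5554,-1.9841,30
-1.2354,-1.9841,39
-0.9154,-1.9841,37
-0.5954,-1.9841,37
-0.2754,-1.9841,49
0.0446,-1.9841,46
0.3646,-1.9841,37
0.6846,-1.9841,35
1.0046,-1.9841,40
1.3246,-1.9841,46
1.6446,-1.9841,54
-1.2354,-1.6641,38
-0.9154,-1.6641,46
-0.5954,-1.6641,43
-0.2754,-1.6641,48
0.0446,-1.6641,52
0.3646,-1.6641,48
0.6846,-1.6641,37
1.0046,-1.6641,50
1.3246,-1.6641,38
1.9646,-1.6641,37
-2.1954,-1.3441,25
-1.8754,-1.3441,38
-1.5554,-1.3441,31
-0.9154,-1.3441,41
-0.5954,-1.3441,45
-0.2754,-1.3441,39
0.0446,-1.3441,50
0.3646,-1.3441,57
0.6846,-1.3441,67
1.0046,-1.3441,47
1.6446,-1.3441,31
1.9646,-1.3441,37
-2.1954,-1.0241,39
-1.8754,-1.0241,31
-1.5554,-1.0241,46
-1.2354,-1.0241,35
-0.9154,-1.0241,29
-0.5954,-1.0241,51
-0.2754,-1.0241,68
0.0446,-1.0241,63
0.3646,-1.0241,63
0.6846,-1.0241,51
1.3246,-1.0241,61
1.6446,-1.0241,55
1.9646,-1.0241,46
2.2846,-1.0241,33
-2.5154,-0.7041,31
-2.1954,-0.7041,25
-1.8754,-0.7041,36
-1.5554,-0.7041,42
-1.2354,-0.7041,26
-0.9154,-0.7041,43
-0.5954,-0.7041,58
-0.2754,-0.7041,59
0.0446,-0.7041,52
0.3646,-0.7041,67
0.6846,-0.7041,76
1.0046,-0.7041,59
1.3246,-0.7041,68
1.6446,-0.7041,46
1.9646,-0.7041,48
2.2846,-0.7041,33
-2.5154,-0.3841,33
-2.1954,-0.3841,24
-1.8754,-0.3841,21
-1.5554,-0.3841,38
-1.2354,-0.3841,19
-0.9154,-0.3841,25
-0.5954,-0.3841,47
-0.2754,-0.3841,45
0.0446,-0.3841,50
0.3646,-0.3841,43
0.6846,-0.3841,54
1.0046,-0.3841,71
1.3246,-0.3841,68
1.6446,-0.3841,52
1.9646,-0.3841,57
2.2846,-0.3841,27
-2.5154,-0.0641,35
-2.1954,-0.0641,21
-1.8754,-0.0641,28
-1.5554,-0.0641,22
-1.2354,-0.0641,54
-0.9154,-0.0641,39
-0.5954,-0.0641,38
-0.2754,-0.0641,24
0.0446,-0.0641,43
0.3646,-0.0641,49
0.6846,-0.0641,61
1.0046,-0.0641,44
1.3246,-0.0641,70
1.6446,-0.0641,60
1.9646,-0.0641,36
2.2846,-0.0641,39
2.6046,-0.0641,29
-2.5154,0.2559,30
-2.1954,0.2559,31
-1.8754,0.2559,34
-1.5554,0.2559,38
-1.2354,0.2559,36
-0.9154,0.2559,55
-0.5954,0.2559,62
-0.2754,0.2559,31
0.0446,0.2559,42
0.3646,0.2559,50
0.6846,0.2559,56
1.0046,0.2559,47
1.3246,0.2559,57
1.6446,0.2559,34
1.9646,0.2559,56
2.2846,0.2559,50
2.6046,0.2559,38
-2.5154,0.5759,25
-2.1954,0.5759,22
-1.8754,0.5759,26
-1.5554,0.5759,40
-1.2354,0.5759,41
-0.9154,0.5759,61
-0.5954,0.5759,52
-0.2754,0.5759,66
0.0446,0.5759,62
0.3646,0.5759,48
0.6846,0.5759,63
1.0046,0.5759,59
1.3246,0.5759,66
1.6446,0.5759,40
1.9646,0.5759,43
2.2846,0.5759,43
-2.1954,0.8959,37
-1.8754,0.8959,30
-1.5554,0.8959,41
-1.2354,0.8959,54
-0.9154,0.8959,61
-0.5954,0.8959,57
-0.2754,0.8959,48
0.0446,0.8959,70
0.3646,0.8959,49
0.6846,0.8959,55
1.0046,0.8959,75
1.3246,0.8959,58
1.6446,0.8959,49
1.9646,0.8959,45
2.2846,0.8959,25
-2.1954,1.2159,21
-1.8754,1.2159,37
-1.5554,1.2159,43
-0.9154,1.2159,60
-0.5954,1.2159,68
-0.2754,1.2159,52
0.0446,1.2159,64
0.3646,1.2159,74
0.6846,1.2159,61
1.0046,1.2159,56
1.6446,1.2159,32
1.9646,1.2159,48
2.2846,1.2159,35
-1.8754,1.5359,38
-1.2354,1.5359,41
-0.9154,1.5359,51
-0.5954,1.5359,50
-0.2754,1.5359,72
0.0446,1.5359,58
0.3646,1.5359,60
0.6846,1.5359,65
1.0046,1.5359,55
1.3246,1.5359,58
1.9646,1.5359,32
-1.5554,1.8559,23
-1.2354,1.8559,52
-0.9154,1.8559,52
-0.5954,1.8559,31
-0.2754,1.8559,62
0.0446,1.8559,54
0.3646,1.8559,40
0.6846,1.8559,51
1.0046,1.8559,50
1.3246,1.8559,33
-1.2354,2.1759,35
-0.9154,2.1759,40
-0.5954,2.1759,55
-0.2754,2.1759,48
0.0446,2.1759,46
0.3646,2.1759,49
0.6846,2.1759,34
1.0046,2.1759,50
1.3246,2.1759,36
-0.5954,2.4959,36
-0.2754,2.4959,38
0.0446,2.4959,29
0.3646,2.4959,24
0.6846,2.4959,30
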